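"""Synthetic digital-phenotyping cohort generator.

Emulates a 40-participant, six-month remote ALS observation study: each
participant wears either a wrist activity monitor (minute-level activity
counts with a wear flag) or an ankle step monitor (minute-level step sums),
and completes smartphone self-entry surveys (ALSFRS-RSE and normed ROADS)
every 2-4 weeks, with the staff-administered ALSFRS-R at months 0, 3 and 6.

The generative model
--------------------
A participant carries a latent severity trajectory ``l0 + l1 * t`` (t in
months) plus instrument-specific random intercepts/slopes. Survey scores are

    score = baseline + slope * t + b0 + b1 * t + loading * (l0 + l1 * t) + eps,

rounded to integers and clipped to the instrument's admissible range; the
self-entry ALSFRS baseline is the staff baseline plus the self-report offset.
Daily activity totals follow the same linear random-slope law on the natural
outcome scale (activity counts or steps per day), coupled to the latent
severity through ``latent_coupling``; totals are floored at zero. Minute
grids allocate each day's total across 1440 minutes with a circadian profile
times bursty gamma weights, then overlay non-wear blocks and charging gaps.

Per-participant RNG substreams are spawned from the master seed keyed by
participant index, so adding a participant never perturbs the others.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from datetime import date as Date
from datetime import timedelta

import numpy as np
import pandas as pd

from .config import (
    ACTIGRAPH,
    ALSFRS_R,
    ALSFRS_RSE,
    DAYS_PER_MONTH,
    MINUTES_PER_DAY,
    MODUS,
    ROADS,
    CohortConfig,
)
from .grids import MinuteDayGrid

SELF_ENTRY_INSTRUMENTS = (ALSFRS_RSE, ROADS)


@dataclass
class ParticipantProfile:
    """Realized participant-level random quantities."""

    participant_id: str
    device: str
    baseline_date: Date
    # per-stream (intercept, slope) random effects
    b_alsfrs: tuple[float, float]
    b_roads: tuple[float, float]
    b_activity: tuple[float, float]
    latent: tuple[float, float]  # (l0, l1) severity trajectory

    def activity_line(self, config: CohortConfig) -> tuple[float, float]:
        """Participant's (intercept, slope) of the expected daily total."""
        act = config.activity(self.device)
        l0, l1 = self.latent
        u0, u1 = self.b_activity
        return (
            act.baseline + u0 + act.latent_coupling * l0,
            act.slope + u1 + act.latent_coupling * l1,
        )

    def survey_line(self, config: CohortConfig, instrument: str) -> tuple[float, float]:
        """Participant's (intercept, slope) of the expected survey score."""
        sp = config.surveys
        if instrument == ROADS:
            b0, b1 = self.b_roads
            loading = sp.roads_latent_loading
        else:
            b0, b1 = self.b_alsfrs
            loading = sp.alsfrs_latent_loading
        l0, l1 = self.latent
        return (
            sp.baseline(instrument) + b0 + loading * l0,
            sp.slope(instrument) + b1 + loading * l1,
        )


@dataclass
class Cohort:
    """Bundle of everything the generator produced."""

    config: CohortConfig
    profiles: list[ParticipantProfile]
    surveys: pd.DataFrame  # participant_id, date, instrument, score, t_months
    daily_truth: pd.DataFrame  # participant_id, date, day_index, t_months, true_total
    truth: pd.DataFrame  # one row per participant: realized random effects
    grids: list[MinuteDayGrid] = field(default_factory=list)

    def device_of(self) -> dict[str, str]:
        return {p.participant_id: p.device for p in self.profiles}


def _participant_rng(
    master_seed: int, index: int, stream: int = 0
) -> np.random.Generator:
    """Independent substream keyed by (participant index, data stream).

    Separate streams for profile, daily totals, minute grids and surveys
    mean that skipping minute-level generation never perturbs the surveys.
    """
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(index, stream))
    )


def _draw_bivariate(rng: np.random.Generator, re) -> tuple[float, float]:
    cov = re.covariance()
    # Cholesky of a possibly singular PSD matrix via eigen decomposition
    w, v = np.linalg.eigh(cov)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal(2)
    b = root @ z
    return float(b[0]), float(b[1])


def generate_profile(
    config: CohortConfig, index: int, device: str, rng: np.random.Generator
) -> ParticipantProfile:
    l0 = rng.normal(0.0, config.latent_intercept_sd)
    l1 = rng.normal(0.0, config.latent_slope_sd)
    b_als = _draw_bivariate(rng, config.surveys.alsfrs_re)
    b_roads = _draw_bivariate(rng, config.surveys.roads_re)
    b_act = _draw_bivariate(rng, config.activity(device).re)
    return ParticipantProfile(
        participant_id=f"P{index + 1:03d}",
        device=device,
        baseline_date=config.start_date,
        b_alsfrs=b_als,
        b_roads=b_roads,
        b_activity=b_act,
        latent=(float(l0), float(l1)),
    )


# ---------------------------------------------------------------------------
# daily activity totals


def simulate_daily_totals(
    config: CohortConfig, profile: ParticipantProfile, rng: np.random.Generator
) -> np.ndarray:
    """True daily activity totals for the whole observation period.

    Linear participant trajectory plus i.i.d. day-level noise, floored at
    zero (a daily total cannot be negative).
    """
    act = config.activity(profile.device)
    days = np.arange(config.observation_days)
    t = days / DAYS_PER_MONTH
    a0, a1 = profile.activity_line(config)
    noise = rng.normal(0.0, act.residual_sd, size=config.observation_days)
    return np.clip(a0 + a1 * t + noise, 0.0, None)


def _circadian_profile(
    config: CohortConfig, night_level: float | None = None
) -> np.ndarray:
    c = config.circadian
    night = c.night_level if night_level is None else night_level
    m = np.arange(MINUTES_PER_DAY, dtype=float)
    profile = np.full(MINUTES_PER_DAY, night)
    wake = (m >= c.wake_start_minute) & (m < c.wake_end_minute)
    span = c.wake_end_minute - c.wake_start_minute
    phase = (m[wake] - c.wake_start_minute) / span
    # raised-cosine bump over the waking window
    profile[wake] = night + 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
    return profile


def _apportion(total: float, weights: np.ndarray) -> np.ndarray:
    """Integer minute values proportional to weights, summing to round(total).

    Largest-remainder apportionment with a stable tie-break, so a day's
    minute values always add back to its (integer-rounded) true total.
    """
    target = int(round(total))
    wsum = weights.sum()
    if target <= 0 or wsum <= 0:
        return np.zeros(MINUTES_PER_DAY)
    raw = weights / wsum * target
    base = np.floor(raw)
    shortfall = int(target - base.sum())
    if shortfall > 0:
        order = np.argsort(-(raw - base), kind="stable")[:shortfall]
        base[order] += 1
    return base


def generate_minute_day(
    config: CohortConfig,
    profile: ParticipantProfile,
    day_index: int,
    rng: np.random.Generator,
    daily_total: float | None = None,
) -> MinuteDayGrid:
    """One participant-day minute grid.

    The day's true total is spread over minutes proportionally to the
    circadian profile times gamma burst weights, rounded to integer counts.
    Wrist-device days then receive non-wear blocks (wear flag off, value 0 --
    an unworn device records essentially nothing) and, with configured
    probability, one charging gap of missing data.
    """
    if not 0 <= day_index < config.observation_days:
        raise ValueError(
            f"day_index {day_index} outside [0, {config.observation_days})"
        )
    act = config.activity(profile.device)
    if daily_total is None:
        t = day_index / DAYS_PER_MONTH
        a0, a1 = profile.activity_line(config)
        daily_total = max(
            0.0, a0 + a1 * t + rng.normal(0.0, act.residual_sd)
        )

    # ankle-device wearers remove the device for sleep: no night steps
    night = 0.0 if profile.device == MODUS else None
    base = _circadian_profile(config, night_level=night)
    shape = act.minute_gamma_shape
    bursts = rng.gamma(shape, 1.0 / shape, size=MINUTES_PER_DAY)
    values = _apportion(daily_total, base * bursts)

    missing = np.zeros(MINUTES_PER_DAY, dtype=bool)
    day_date = profile.baseline_date + timedelta(days=day_index)

    if profile.device == MODUS:
        return MinuteDayGrid(
            participant_id=profile.participant_id,
            date=day_date,
            device=MODUS,
            values=values,
            missing=missing,
        )

    wear = np.ones(MINUTES_PER_DAY, dtype=bool)
    miss = config.missingness
    n_blocks = rng.poisson(miss.nonwear_blocks_mean)
    for _ in range(n_blocks):
        length = int(
            np.clip(
                rng.exponential(miss.nonwear_block_minutes_mean),
                miss.nonwear_block_minutes_min,
                miss.nonwear_block_minutes_max,
            )
        )
        start = int(rng.integers(0, MINUTES_PER_DAY))
        stop = min(start + length, MINUTES_PER_DAY)
        wear[start:stop] = False
    if rng.random() < miss.charging_gap_prob and miss.charging_gap_minutes > 0:
        gap = miss.charging_gap_minutes
        start = int(rng.integers(0, max(1, MINUTES_PER_DAY - gap + 1)))
        missing[start : start + gap] = True

    values = values.copy()
    values[~wear] = 0.0  # off-body device records no movement
    values[missing] = np.nan
    return MinuteDayGrid(
        participant_id=profile.participant_id,
        date=day_date,
        device=ACTIGRAPH,
        values=values,
        missing=missing,
        wear=wear,
    )


# ---------------------------------------------------------------------------
# surveys


def survey_schedule(
    config: CohortConfig, rng: np.random.Generator
) -> list[int]:
    """Self-entry survey event days: day 0, then 2-4 week gaps."""
    lo, hi = config.survey_interval_days
    days = [0]
    while True:
        nxt = days[-1] + int(rng.integers(lo, hi + 1))
        if nxt >= config.observation_days:
            break
        days.append(nxt)
    return days


def staff_visit_days(config: CohortConfig) -> list[int]:
    """Staff ALSFRS-R administration days (months 0/3/6, clamped to period)."""
    out = []
    for m in config.staff_visit_months:
        d = int(round(m * DAYS_PER_MONTH))
        out.append(min(d, config.observation_days - 1))
    return sorted(set(out))


def generate_survey_trajectory(
    config: CohortConfig,
    profile: ParticipantProfile,
    instrument: str,
    schedule_days: list[int],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Scores for one instrument at the scheduled days.

    score = participant line at t, plus residual noise, rounded to the
    integer scale and clipped to the admissible range. The self-report
    offset enters only the self-entry ALSFRS baseline (via the config).
    """
    if not schedule_days:
        raise ValueError("schedule must be non-empty")
    sp = config.surveys
    lo, hi = sp.score_range(instrument)
    a, b = profile.survey_line(config, instrument)
    rows = []
    for d in schedule_days:
        if not 0 <= d < config.observation_days:
            raise ValueError(f"schedule day {d} outside observation period")
        t = d / DAYS_PER_MONTH
        score = a + b * t + rng.normal(0.0, sp.residual_sd(instrument))
        if sp.round_scores:
            score = np.round(score)
        score = float(np.clip(score, lo, hi))
        rows.append(
            {
                "participant_id": profile.participant_id,
                "date": profile.baseline_date + timedelta(days=d),
                "instrument": instrument,
                "score": score,
                "t_months": t,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort assembly


def generate_cohort(config: CohortConfig, minute_level: bool = True) -> Cohort:
    """Generate the full cohort bundle; deterministic given the master seed.

    With ``minute_level=False`` only the daily activity totals and surveys
    are produced (identical daily law, no 1440-minute expansion) -- the
    resolution used for replicate-heavy parameter-recovery studies.
    """
    config.validate()
    n_actigraph = int(round(config.n_participants * config.device_split))
    profiles: list[ParticipantProfile] = []
    survey_frames: list[pd.DataFrame] = []
    daily_rows: list[pd.DataFrame] = []
    grids: list[MinuteDayGrid] = []
    truth_rows = []
    staff_days = staff_visit_days(config)

    for i in range(config.n_participants):
        device = ACTIGRAPH if i < n_actigraph else MODUS
        profile = generate_profile(
            config, i, device, _participant_rng(config.master_seed, i, 0)
        )
        profiles.append(profile)

        totals = simulate_daily_totals(
            config, profile, _participant_rng(config.master_seed, i, 1)
        )
        days = np.arange(config.observation_days)
        daily_rows.append(
            pd.DataFrame(
                {
                    "participant_id": profile.participant_id,
                    "date": [
                        profile.baseline_date + timedelta(days=int(d))
                        for d in days
                    ],
                    "day_index": days,
                    "t_months": days / DAYS_PER_MONTH,
                    "true_total": totals,
                }
            )
        )
        if minute_level:
            minute_rng = _participant_rng(config.master_seed, i, 2)
            for d in days:
                grids.append(
                    generate_minute_day(
                        config, profile, int(d), minute_rng,
                        daily_total=totals[d],
                    )
                )

        rng = _participant_rng(config.master_seed, i, 3)
        self_days = survey_schedule(config, rng)
        for instrument in SELF_ENTRY_INSTRUMENTS:
            completed = [
                d
                for d in self_days
                if rng.random() < config.survey_completion_prob
            ]
            if completed:
                survey_frames.append(
                    generate_survey_trajectory(
                        config, profile, instrument, completed, rng
                    )
                )
        # staff-administered scale: months 0/3/6 only, always completed
        survey_frames.append(
            generate_survey_trajectory(
                config, profile, ALSFRS_R, staff_days, rng
            )
        )

        a0, a1 = profile.activity_line(config)
        truth_rows.append(
            {
                "participant_id": profile.participant_id,
                "device": device,
                "latent_intercept": profile.latent[0],
                "latent_slope": profile.latent[1],
                "alsfrs_b0": profile.b_alsfrs[0],
                "alsfrs_b1": profile.b_alsfrs[1],
                "roads_b0": profile.b_roads[0],
                "roads_b1": profile.b_roads[1],
                "activity_b0": profile.b_activity[0],
                "activity_b1": profile.b_activity[1],
                "activity_intercept_total": a0,
                "activity_slope_total": a1,
            }
        )

    surveys = (
        pd.concat(survey_frames, ignore_index=True)
        if survey_frames
        else pd.DataFrame(
            columns=["participant_id", "date", "instrument", "score", "t_months"]
        )
    )
    return Cohort(
        config=config,
        profiles=profiles,
        surveys=surveys,
        daily_truth=pd.concat(daily_rows, ignore_index=True),
        truth=pd.DataFrame(truth_rows),
        grids=grids,
    )


def cohort_checksum(cohort: Cohort) -> str:
    """Content hash over every generated artifact (reproducibility checks)."""
    h = hashlib.sha256()
    for df in (cohort.surveys, cohort.daily_truth, cohort.truth):
        h.update(df.to_csv(index=False).encode())
    for g in cohort.grids:
        h.update(str(g.participant_id).encode())
        h.update(str(g.date).encode())
        h.update(np.nan_to_num(g.values, nan=-1.0).tobytes())
        h.update(g.missing.tobytes())
        if g.wear is not None:
            h.update(g.wear.tobytes())
    return h.hexdigest()
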