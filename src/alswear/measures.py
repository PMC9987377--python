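"""Daily physical-activity summary measures.

Wrist-device (activity-count) investigator-derived measures, computed from
imputed 1440-minute days:

- ``tac``: total activity counts, the 24-hour AC sum;
- ``log_tac``: ln(TAC + 1);
- ``total_log_ac``: the 24-hour sum of ln(AC + 1);
- ``active_minutes`` / ``sedentary_minutes``: minutes with AC strictly above
  / at-or-below the activity threshold (default 1853); they always add up
  to 1440;
- ``astp`` / ``satp``: active-to-sedentary and sedentary-to-active
  transition probabilities -- the fragmentation measures: the conditional
  probability that a minute is sedentary given the previous minute was
  active, and vice versa. Undefined (NaN) when no minute of the
  conditioning state exists before the final minute.

Ankle-device (step) measures, computed from raw minute step sums on valid
days: total steps; mean, median and 95th-percentile cadence over minutes
with at least one step; percent time in the 1-15 / 16-40 / 41+ steps-per-
minute bands (denominator: minutes inside valid hours); maximum consecutive
cadence over 60-, 20-, 5- and 1-minute windows; and the peak performance
index (mean cadence of the day's 30 most intensive, non-contiguous minutes).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ACTIGRAPH, MINUTES_PER_DAY, MODUS
from .grids import ImputedDayGrid, MinuteDayGrid
from .validity import DayValidity, day_validity

DEFAULT_ACTIVE_THRESHOLD = 1853.0

ACTIGRAPH_MEASURES = (
    "tac",
    "log_tac",
    "total_log_ac",
    "active_minutes",
    "sedentary_minutes",
    "astp",
    "satp",
)

MODUS_MEASURES = (
    "total_steps",
    "cadence_mean",
    "cadence_median",
    "cadence_p95",
    "pct_low",
    "pct_medium",
    "pct_high",
    "max_cadence_60",
    "max_cadence_20",
    "max_cadence_5",
    "max_cadence_1",
    "ppi",
)


# ---------------------------------------------------------------------------
# actigraph investigator-derived measures


def total_activity_counts(day: ImputedDayGrid) -> float:
    return float(day.values.sum())


def log_total_activity_counts(day: ImputedDayGrid) -> float:
    return float(np.log1p(day.values.sum()))


def total_log_activity_counts(day: ImputedDayGrid) -> float:
    return float(np.log1p(day.values).sum())


def active_sedentary_minutes(
    day: ImputedDayGrid, threshold: float = DEFAULT_ACTIVE_THRESHOLD
) -> tuple[int, int]:
    """Strict inequality: a minute exactly at the threshold is sedentary."""
    active = int((day.values > threshold).sum())
    return active, MINUTES_PER_DAY - active


def transition_probabilities(
    day: ImputedDayGrid, threshold: float = DEFAULT_ACTIVE_THRESHOLD
) -> tuple[float, float]:
    """(ASTP, SATP) for one day; transitions never wrap across midnight.

    Denominators count minutes of the conditioning state among minutes
    0..1438 (the final minute has no successor). A zero denominator yields
    NaN, never 0.
    """
    active = day.values > threshold
    return _transitions_from_labels(active)


def _transitions_from_labels(active: np.ndarray) -> tuple[float, float]:
    a, nxt = active[:-1], active[1:]
    n_active = int(a.sum())
    n_sed = int((~a).sum())
    astp = float((a & ~nxt).sum() / n_active) if n_active else float("nan")
    satp = float((~a & nxt).sum() / n_sed) if n_sed else float("nan")
    return astp, satp


# ---------------------------------------------------------------------------
# modus step/cadence measures


def modus_daily_steps(day: MinuteDayGrid) -> float:
    return float(np.nan_to_num(day.values, nan=0.0).sum())


def _stepping_minutes(day: MinuteDayGrid) -> np.ndarray:
    v = np.nan_to_num(day.values, nan=0.0)
    return v[v >= 1]


def cadence_statistics(day: MinuteDayGrid) -> tuple[float, float, float]:
    """(mean, median, p95) steps/minute over minutes with >= 1 step.

    NaN triple if no stepping minute. The 95th percentile uses linear
    interpolation between order statistics.
    """
    stepping = _stepping_minutes(day)
    if stepping.size == 0:
        return float("nan"), float("nan"), float("nan")
    return (
        float(stepping.mean()),
        float(np.median(stepping)),
        float(np.percentile(stepping, 95)),
    )


def percent_time_bands(
    day: MinuteDayGrid,
    validity: DayValidity,
    low: tuple[int, int] = (1, 15),
    medium: tuple[int, int] = (16, 40),
    high_min: int = 41,
) -> tuple[float, float, float]:
    """Percent of valid-hour minutes in the low/medium/high cadence bands.

    Band edges are inclusive integer ranges. Zero-step minutes inside valid
    hours contribute to the denominator but to no band, so the three
    percentages sum to at most 100. All NaN when no valid hour exists.
    """
    in_valid_hour = np.repeat(validity.valid_hour_flags, 60)
    denom = int(in_valid_hour.sum())
    if denom == 0:
        return float("nan"), float("nan"), float("nan")
    v = np.nan_to_num(day.values, nan=0.0)[in_valid_hour]
    pct = lambda mask: float(100.0 * mask.sum() / denom)  # noqa: E731
    return (
        pct((v >= low[0]) & (v <= low[1])),
        pct((v >= medium[0]) & (v <= medium[1])),
        pct(v >= high_min),
    )


def max_consecutive_cadence(day: MinuteDayGrid, window: int) -> float:
    """Best mean steps/minute over any contiguous run of `window` minutes.

    Requires a full window; ``window`` must be in [1, 1440].
    """
    if not 1 <= window <= MINUTES_PER_DAY:
        raise ValueError(f"window must be in [1, 1440], got {window}")
    v = np.nan_to_num(day.values, nan=0.0)
    sums = np.convolve(v, np.ones(window), mode="valid")
    return float(sums.max() / window)


def peak_performance_index(day: MinuteDayGrid, top: int = 30) -> float:
    """Mean cadence of the day's `top` most intensive non-contiguous minutes."""
    v = np.nan_to_num(day.values, nan=0.0)
    if v.size < top:
        raise ValueError(f"day must span at least {top} minutes")
    idx = np.argpartition(v, -top)[-top:]
    return float(v[idx].mean())


# ---------------------------------------------------------------------------
# long-format assembly


def actigraph_day_measures(
    day: ImputedDayGrid, threshold: float = DEFAULT_ACTIVE_THRESHOLD
) -> dict[str, float]:
    active, sedentary = active_sedentary_minutes(day, threshold)
    astp, satp = transition_probabilities(day, threshold)
    return {
        "tac": total_activity_counts(day),
        "log_tac": log_total_activity_counts(day),
        "total_log_ac": total_log_activity_counts(day),
        "active_minutes": float(active),
        "sedentary_minutes": float(sedentary),
        "astp": astp,
        "satp": satp,
    }


def modus_day_measures(
    day: MinuteDayGrid,
    validity: DayValidity | None = None,
    low: tuple[int, int] = (1, 15),
    medium: tuple[int, int] = (16, 40),
    high_min: int = 41,
) -> dict[str, float]:
    if validity is None:
        validity = day_validity(day)
    mean, median, p95 = cadence_statistics(day)
    plow, pmed, phigh = percent_time_bands(day, validity, low, medium, high_min)
    out = {
        "total_steps": modus_daily_steps(day),
        "cadence_mean": mean,
        "cadence_median": median,
        "cadence_p95": p95,
        "pct_low": plow,
        "pct_medium": pmed,
        "pct_high": phigh,
        "ppi": peak_performance_index(day),
    }
    for w in (60, 20, 5, 1):
        out[f"max_cadence_{w}"] = max_consecutive_cadence(day, w)
    return out


def derive_all(
    actigraph_days: list[ImputedDayGrid],
    modus_days: list[MinuteDayGrid],
    threshold: float = DEFAULT_ACTIVE_THRESHOLD,
    cadence_low: tuple[int, int] = (1, 15),
    cadence_medium: tuple[int, int] = (16, 40),
    cadence_high_min: int = 41,
) -> pd.DataFrame:
    """Long-format daily-measure table: one row per participant-day-measure.

    Inputs must already be validity-filtered, and the wrist-device days
    imputed. Wrist participants contribute the 7 investigator-derived
    measures per day; ankle participants the 12 step/cadence measures.
    """
    rows = []
    for day in actigraph_days:
        for name, value in actigraph_day_measures(day, threshold).items():
            rows.append(
                (day.participant_id, day.date, ACTIGRAPH, name, value)
            )
    for day in modus_days:
        measures = modus_day_measures(
            day, None, cadence_low, cadence_medium, cadence_high_min
        )
        for name in MODUS_MEASURES:
            rows.append(
                (day.participant_id, day.date, MODUS, name, measures[name])
            )
    return pd.DataFrame(
        rows, columns=["participant_id", "date", "device", "measure", "value"]
    )
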