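"""Survey trajectory models and the staff- vs self-entry comparison.

Six random-slope LMMs on the survey total scores: per-instrument
trajectories (self-entry ALSFRS-RSE, normed ROADS, staff ALSFRS-R), the
stacked ALSFRS model with a self-entry indicator and its interaction with
time, and the device-group models with an ankle-device (Modus) indicator.
Plus the matched Pearson correlation between staff and self-entry ALSFRS at
each staff administration (baseline / 3 / 6 months), pairing each staff
score with the participant's closest self-entry score within +/- 28 days.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .config import ALSFRS_R, ALSFRS_RSE, MODUS, ROADS
from .model import ProgressionModel, ProgressionResults

logger = logging.getLogger(__name__)

MIN_SUBMISSIONS = 2  # analysis sample: >=2 complete of each self-entry scale


def analysis_sample(surveys: pd.DataFrame) -> pd.DataFrame:
    """Restrict to participants with >= 2 complete ALSFRS-RSE and ROADS."""
    counts = (
        surveys.groupby(["participant_id", "instrument"]).size().unstack(
            fill_value=0
        )
    )
    ok = counts.index[
        (counts.get(ALSFRS_RSE, 0) >= MIN_SUBMISSIONS)
        & (counts.get(ROADS, 0) >= MIN_SUBMISSIONS)
    ]
    return surveys[surveys["participant_id"].isin(ok)].copy()


def fit_trajectory_models(
    surveys: pd.DataFrame, apply_sample_filter: bool = True
) -> dict[str, ProgressionResults]:
    """Models 1-3: score ~ time with random intercept + slope, per instrument."""
    if apply_sample_filter:
        surveys = analysis_sample(surveys)
    out = {}
    for instrument in (ALSFRS_RSE, ROADS, ALSFRS_R):
        sub = surveys[surveys["instrument"] == instrument]
        if sub.empty:
            continue
        out[instrument] = ProgressionModel(sub, "score").fit()
    return out


def fit_combined_scale_model(
    surveys: pd.DataFrame, apply_sample_filter: bool = True
) -> ProgressionResults:
    """Model 4: stacked ALSFRS-R + ALSFRS-RSE scores with a self-entry
    indicator and its interaction with time.

    The indicator coefficient estimates the self-entry baseline offset; the
    interaction estimates the slope difference between the scales.
    """
    if apply_sample_filter:
        surveys = analysis_sample(surveys)
    sub = surveys[surveys["instrument"].isin([ALSFRS_R, ALSFRS_RSE])].copy()
    present = set(sub["instrument"].unique())
    if present != {ALSFRS_R, ALSFRS_RSE}:
        raise ValueError(
            "combined-scale model needs both ALSFRS variants; "
            f"got {sorted(present)}"
        )
    sub["self_entry"] = (sub["instrument"] == ALSFRS_RSE).astype(float)
    sub["self_entry_x_time"] = sub["self_entry"] * sub["t_months"]
    return ProgressionModel(
        sub, "score", extra_fixed=("self_entry", "self_entry_x_time")
    ).fit()


def fit_device_group_models(
    surveys: pd.DataFrame,
    devices: dict[str, str],
    apply_sample_filter: bool = True,
) -> dict[str, ProgressionResults]:
    """Models 5-6: per self-entry instrument, add an ankle-device indicator
    and its interaction with time."""
    if apply_sample_filter:
        surveys = analysis_sample(surveys)
    out = {}
    for instrument in (ALSFRS_RSE, ROADS):
        sub = surveys[surveys["instrument"] == instrument].copy()
        sub["modus"] = (
            sub["participant_id"].map(devices).eq(MODUS).astype(float)
        )
        if sub["modus"].nunique() < 2:
            raise ValueError("device-group model needs both device groups")
        sub["modus_x_time"] = sub["modus"] * sub["t_months"]
        out[instrument] = ProgressionModel(
            sub, "score", extra_fixed=("modus", "modus_x_time")
        ).fit()
    return out


def matched_pearson(
    surveys: pd.DataFrame,
    window_days: int = 28,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Pearson r between staff and self-entry ALSFRS at each staff visit.

    Staff administrations are labelled by the nearest of months 0/3/6. For
    each, a participant contributes the self-entry score with the smallest
    absolute date offset within the window; equidistant ties break toward
    the earlier survey. Timepoints with fewer than `min_pairs` pairs get a
    missing correlation with a warning.
    """
    staff = surveys[surveys["instrument"] == ALSFRS_R].copy()
    rse = surveys[surveys["instrument"] == ALSFRS_RSE]
    staff["timepoint"] = staff["t_months"].map(
        lambda t: min((0.0, 3.0, 6.0), key=lambda m: abs(t - m))
    )
    rows = []
    for tp, visits in staff.groupby("timepoint"):
        pairs = []
        for _, visit in visits.iterrows():
            cand = rse[rse["participant_id"] == visit["participant_id"]]
            if cand.empty:
                continue
            offsets = (
                pd.to_datetime(cand["date"]) - pd.to_datetime(visit["date"])
            ).dt.days
            eligible = cand[offsets.abs() <= window_days]
            if eligible.empty:
                continue
            off = offsets[eligible.index]
            # min |offset|; ties toward the earlier (negative-offset) survey
            best = eligible.loc[
                off.map(lambda d: (abs(d), d)).sort_values().index[0]
            ]
            pairs.append((visit["score"], best["score"]))
        r = np.nan
        if len(pairs) >= min_pairs:
            a, b = np.array(pairs).T
            if np.std(a) > 0 and np.std(b) > 0:
                r = float(stats.pearsonr(a, b)[0])
        else:
            logger.warning(
                "timepoint %s months: only %d matched pairs (<%d); "
                "correlation missing", tp, len(pairs), min_pairs,
            )
        rows.append({"timepoint_months": tp, "n_pairs": len(pairs), "r": r})
    return pd.DataFrame(rows).sort_values("timepoint_months", ignore_index=True)
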