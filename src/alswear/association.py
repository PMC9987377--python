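"""Associations between daily wearable measures and survey scores.

For each daily measure and each self-entry survey, the covariate at a
survey is the mean of the measure's valid-day values in the 15-day window
spanning 7 days before through 7 days after the survey date. Covariates are
standardized (zero mean, unit SD) over the observations entering each model,
then a random intercept + random-slope-on-covariate LMM of the survey score
on the standardized covariate is fitted. A measure counts as "significant
for both surveys" when its covariate reaches p < 0.05 in both models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ALSFRS_RSE, ROADS
from .model import ProgressionModel, ProgressionResults

DEFAULT_HALF_WINDOW = 7


def build_covariates(
    daily: pd.DataFrame,
    surveys: pd.DataFrame,
    half_window: int = DEFAULT_HALF_WINDOW,
) -> pd.DataFrame:
    """Windowed raw covariates: one row per (survey observation, measure).

    `daily` is the long-format valid-day measure table. Surveys with no
    valid day in the window get a missing covariate (dropped at fit time).
    """
    daily = daily.copy()
    daily["date"] = pd.to_datetime(daily["date"])
    surveys = surveys.copy()
    surveys["date"] = pd.to_datetime(surveys["date"])
    rows = []
    for (pid, measure), sub in daily.groupby(["participant_id", "measure"]):
        svy = surveys[surveys["participant_id"] == pid]
        for idx, s in svy.iterrows():
            delta = (sub["date"] - s["date"]).dt.days
            vals = sub.loc[delta.abs() <= half_window, "value"].dropna()
            rows.append(
                {
                    "survey_index": idx,
                    "participant_id": pid,
                    "survey_date": s["date"],
                    "instrument": s["instrument"],
                    "score": s["score"],
                    "t_months": s["t_months"],
                    "measure": measure,
                    "window_mean": vals.mean() if len(vals) else np.nan,
                    "n_days_in_window": int(len(vals)),
                }
            )
    return pd.DataFrame(rows)


def standardize(values: pd.Series | np.ndarray) -> np.ndarray:
    """(x - mean) / SD with the n-1 (sample) SD convention."""
    x = np.asarray(values, dtype=float)
    if np.sum(~np.isnan(x)) < 2:
        raise ValueError("standardization needs >= 2 non-missing values")
    sd = np.nanstd(x, ddof=1)
    if sd == 0:
        raise ValueError("zero spread: covariate is uninformative")
    return (x - np.nanmean(x)) / sd


def fit_associations(
    covariates: pd.DataFrame,
    instruments: tuple[str, ...] = (ALSFRS_RSE, ROADS),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One LMM per (measure, instrument): score ~ z(covariate) with random
    intercept and random slope on the covariate.

    Returns a tidy table with the covariate estimate, 95% CI, p-value,
    R2m/R2c and a per-measure "significant for both surveys" flag.
    """
    rows = []
    for (measure, instrument), sub in covariates.groupby(
        ["measure", "instrument"]
    ):
        if instrument not in instruments:
            continue
        sub = sub.dropna(subset=["window_mean", "score"]).copy()
        if len(sub) < 3 or sub["participant_id"].nunique() < 2:
            continue
        try:
            sub["z"] = standardize(sub["window_mean"])
        except ValueError:
            continue
        fit = ProgressionModel(
            sub,
            "score",
            extra_fixed=("z",),
            random_slope_on="z",
            include_time=False,
        ).fit()
        r2m, r2c = fit.r2() if fit.converged else (np.nan, np.nan)
        rows.append(
            {
                "measure": measure,
                "instrument": instrument,
                "estimate": fit.params["z"],
                "ci_low": fit.conf_int.loc["z", "ci_low"],
                "ci_high": fit.conf_int.loc["z", "ci_high"],
                "p": fit.pvalues["z"],
                "r2m": r2m,
                "r2c": r2c,
                "converged": fit.converged,
                "n_obs": fit.n_obs,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    sig = (
        (table["p"] < alpha)
        .groupby([table["measure"], table["instrument"]])
        .any()
        .unstack()
    )
    both = sig.reindex(columns=list(instruments)).fillna(False).all(axis=1)
    table["significant_both_surveys"] = table["measure"].map(both)
    return table
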