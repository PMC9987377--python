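"""Replicate simulation studies: parameter recovery, CI coverage, and
monitoring-frequency sensitivity at the default cohort conditions.

These run the generator at daily resolution (the daily trajectory law is
identical to the minute-level path, which preserves daily totals by
construction) so that hundreds of replicate cohorts fit in minutes.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .config import ACTIGRAPH, ALSFRS_R, ALSFRS_RSE, ROADS, CohortConfig
from .model import ProgressionModel
from .sensitivity import default_scenarios, run_sensitivity
from .simulate import generate_cohort
from .surveys import fit_combined_scale_model, fit_trajectory_models


def replicate_seeds(base_seed: int, n: int) -> np.ndarray:
    """Independent master seeds for n replicate cohorts (all < 2^31)."""
    ss = np.random.SeedSequence(base_seed)
    return ss.generate_state(n, dtype=np.uint32).astype(np.int64) % (2**31)


def _replicate_config(config: CohortConfig | None, seed: int) -> CohortConfig:
    cfg = dataclasses.replace(config) if config else CohortConfig()
    cfg.master_seed = int(seed)
    return cfg


def _covers(fit, term: str, truth: float) -> bool:
    lo, hi = fit.conf_int.loc[term]
    return bool(lo <= truth <= hi)


def survey_recovery_study(
    n_replicates: int, base_seed: int, config: CohortConfig | None = None
) -> pd.DataFrame:
    """Per-replicate survey fixed-effect estimates and slope-CI coverage."""
    rows = []
    for seed in replicate_seeds(base_seed, n_replicates):
        cfg = _replicate_config(config, seed)
        cohort = generate_cohort(cfg, minute_level=False)
        fits = fit_trajectory_models(cohort.surveys)
        combined = fit_combined_scale_model(cohort.surveys)
        sp = cfg.surveys
        row = {"seed": int(seed)}
        for inst, key in (
            (ALSFRS_RSE, "alsfrs_rse"),
            (ROADS, "roads"),
            (ALSFRS_R, "alsfrs_r"),
        ):
            fit = fits[inst]
            row[f"{key}_baseline"] = fit.params["Intercept"]
            row[f"{key}_slope"] = fit.params["t_months"]
            row[f"{key}_slope_covered"] = _covers(
                fit, "t_months", sp.slope(inst)
            )
            row[f"{key}_converged"] = fit.converged
        row["offset"] = combined.params["self_entry"]
        row["offset_covered"] = _covers(
            combined, "self_entry", sp.self_report_offset
        )
        row["slope_diff"] = combined.params["self_entry_x_time"]
        rows.append(row)
    return pd.DataFrame(rows)


def tac_recovery_study(
    n_replicates: int, base_seed: int, config: CohortConfig | None = None
) -> pd.DataFrame:
    """Per-replicate total-activity-counts trajectory estimates.

    Fits value ~ time (random intercept + slope) on the wrist-device
    participants' true daily totals.
    """
    rows = []
    for seed in replicate_seeds(base_seed, n_replicates):
        cfg = _replicate_config(config, seed)
        cohort = generate_cohort(cfg, minute_level=False)
        ag = set(
            cohort.truth.loc[
                cohort.truth["device"] == ACTIGRAPH, "participant_id"
            ]
        )
        daily = cohort.daily_truth[
            cohort.daily_truth["participant_id"].isin(ag)
        ].rename(columns={"true_total": "value"})
        fit = ProgressionModel(daily, "value").fit()
        act = cfg.actigraph_activity
        rows.append(
            {
                "seed": int(seed),
                "tac_baseline": fit.params["Intercept"],
                "tac_slope": fit.params["t_months"],
                "tac_slope_covered": _covers(fit, "t_months", act.slope),
                "tac_baseline_covered": _covers(fit, "Intercept", act.baseline),
                "r2m": fit.r2()[0] if fit.converged else np.nan,
                "r2c": fit.r2()[1] if fit.converged else np.nan,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


def sensitivity_study(
    n_replicates: int, base_seed: int, config: CohortConfig | None = None
) -> pd.DataFrame:
    """Per-replicate: does every monitoring scenario detect significant
    negative total-activity-counts decline?"""
    scenarios = default_scenarios()
    rows = []
    for seed in replicate_seeds(base_seed, n_replicates):
        cfg = _replicate_config(config, seed)
        cohort = generate_cohort(cfg, minute_level=False)
        ag = set(
            cohort.truth.loc[
                cohort.truth["device"] == ACTIGRAPH, "participant_id"
            ]
        )
        daily = cohort.daily_truth[
            cohort.daily_truth["participant_id"].isin(ag)
        ].rename(columns={"true_total": "value"})
        out = run_sensitivity(daily, scenarios)
        rows.append(
            {
                "seed": int(seed),
                "all_significant_negative": bool(
                    (out["slope_significant"] & (out["slope_est"] < 0)).all()
                ),
                "max_baseline_deviation_pct": float(
                    out["baseline_pct_deviation"].max()
                ),
                "max_slope_deviation_pct": float(
                    out["slope_pct_deviation"].max()
                ),
            }
        )
    return pd.DataFrame(rows)


def mc_se(values: np.ndarray) -> float:
    """Monte-Carlo standard error of a replicate mean."""
    values = np.asarray(values, dtype=float)
    return float(values.std(ddof=1) / np.sqrt(len(values)))
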