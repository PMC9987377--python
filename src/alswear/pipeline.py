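"""End-to-end orchestration: simulate -> validate -> impute -> derive ->
fit-surveys -> associate -> sensitivity, with persisted intermediates and
content checksums for reproducibility audits."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as aio
from .association import build_covariates, fit_associations
from .config import ACTIGRAPH, ALSFRS_RSE, MODUS, ROADS, CohortConfig
from .imputation import impute_cohort
from .measures import derive_all
from .model import ProgressionModel
from .sensitivity import run_sensitivity
from .simulate import Cohort, generate_cohort
from .surveys import (
    fit_combined_scale_model,
    fit_device_group_models,
    fit_trajectory_models,
    matched_pearson,
)
from .validity import compliance_summary, filter_valid_days

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "validate",
    "impute",
    "derive",
    "fit-surveys",
    "associate",
    "sensitivity",
)


@dataclass
class PipelineRun:
    config: CohortConfig
    out_dir: Path
    checksums: dict[str, str] = field(default_factory=dict)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def record(self, name: str, path: Path) -> None:
        self.checksums[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    def write_manifest(self) -> None:
        manifest = {
            "master_seed": self.config.master_seed,
            "checksums": self.checksums,
        }
        (self.out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )


def run_pipeline(
    config: CohortConfig,
    out_dir: str | Path,
    write_minutes: bool = False,
) -> PipelineRun:
    """Run every stage on a freshly simulated cohort and persist summaries.

    Minute-level CSVs are large; they are written only on request
    (`write_minutes=True`). All stage summary tables are always written and
    checksummed, so a rerun with the same config and seed reproduces
    identical files.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    run = PipelineRun(config=config, out_dir=out_dir)

    logger.info("stage simulate")
    cohort = generate_cohort(config, minute_level=True)
    aio.write_survey_csv(cohort.surveys, out_dir / "surveys.csv")
    aio.write_table_csv(cohort.truth, out_dir / "truth.csv")
    run.record("surveys.csv", out_dir / "surveys.csv")
    run.record("truth.csv", out_dir / "truth.csv")
    if write_minutes:
        aio.write_minute_csv(cohort.grids, out_dir / "minutes.csv")
        run.record("minutes.csv", out_dir / "minutes.csv")

    logger.info("stage validate")
    valid_grids, validity = filter_valid_days(
        cohort.grids, config.valid_hours_per_day
    )
    compliance = compliance_summary(validity, cohort.surveys)
    aio.write_table_csv(validity, out_dir / "validity.csv")
    aio.write_table_csv(compliance, out_dir / "compliance.csv")
    run.record("validity.csv", out_dir / "validity.csv")
    run.record("compliance.csv", out_dir / "compliance.csv")
    run.tables["validity"] = validity
    run.tables["compliance"] = compliance

    logger.info("stage impute")
    imputed = impute_cohort(valid_grids)
    if write_minutes:
        aio.write_minute_csv(imputed, out_dir / "minutes_imputed.csv")
        run.record("minutes_imputed.csv", out_dir / "minutes_imputed.csv")

    logger.info("stage derive")
    modus_days = [g for g in valid_grids if g.device == MODUS]
    daily = derive_all(
        imputed,
        modus_days,
        threshold=config.active_threshold,
        cadence_low=config.cadence_low_band,
        cadence_medium=config.cadence_medium_band,
        cadence_high_min=config.cadence_high_min,
    )
    aio.write_table_csv(daily, out_dir / "daily_measures.csv")
    run.record("daily_measures.csv", out_dir / "daily_measures.csv")
    run.tables["daily_measures"] = daily

    logger.info("stage fit-surveys")
    traj = fit_trajectory_models(cohort.surveys)
    combined = fit_combined_scale_model(cohort.surveys)
    device_fits = fit_device_group_models(cohort.surveys, cohort.device_of())
    fit_rows = []
    for name, fit in [
        *((f"model_{k}", v) for k, v in traj.items()),
        ("model_combined_alsfrs", combined),
        *((f"model_device_{k}", v) for k, v in device_fits.items()),
    ]:
        tbl = fit.fe_table()
        tbl.insert(0, "model", name)
        r2m, r2c = fit.r2() if fit.converged else (float("nan"),) * 2
        tbl["r2m"], tbl["r2c"] = r2m, r2c
        fit_rows.append(tbl)
    survey_fits = pd.concat(fit_rows, ignore_index=True)
    cm_rows = []
    for inst, fit in traj.items():
        if not fit.converged:
            continue
        lines = fit.conditional_lines().reset_index(names="participant_id")
        lines.insert(0, "instrument", inst)
        cm_rows.append(lines)
    conditional_means = (
        pd.concat(cm_rows, ignore_index=True) if cm_rows else pd.DataFrame()
    )
    aio.write_table_csv(
        conditional_means, out_dir / "conditional_means.csv"
    )
    run.record("conditional_means.csv", out_dir / "conditional_means.csv")
    run.tables["conditional_means"] = conditional_means
    corr = matched_pearson(cohort.surveys)
    aio.write_table_csv(survey_fits, out_dir / "survey_fits.csv")
    aio.write_table_csv(corr, out_dir / "alsfrs_correlations.csv")
    run.record("survey_fits.csv", out_dir / "survey_fits.csv")
    run.record("alsfrs_correlations.csv", out_dir / "alsfrs_correlations.csv")
    run.tables["survey_fits"] = survey_fits
    run.tables["alsfrs_correlations"] = corr

    logger.info("stage associate")
    covariates = build_covariates(daily, cohort.surveys)
    associations = fit_associations(covariates)
    aio.write_table_csv(associations, out_dir / "associations.csv")
    run.record("associations.csv", out_dir / "associations.csv")
    run.tables["associations"] = associations

    logger.info("stage sensitivity")
    tac = daily[daily["measure"] == "tac"].copy()
    sens = pd.DataFrame()
    if not tac.empty:
        baseline_dates = tac.groupby("participant_id")["date"].transform("min")
        tac["day_index"] = (
            pd.to_datetime(tac["date"]) - pd.to_datetime(baseline_dates)
        ).dt.days
        tac["t_months"] = tac["day_index"] / 30.4375
        sens = run_sensitivity(tac)
    aio.write_table_csv(sens, out_dir / "sensitivity.csv")
    run.record("sensitivity.csv", out_dir / "sensitivity.csv")
    run.tables["sensitivity"] = sens

    run.write_manifest()
    return run


def fit_daily_measure_models(
    daily: pd.DataFrame, measures: list[str] | None = None
) -> pd.DataFrame:
    """Trajectory LMM (value ~ time) for each daily measure.

    Returns one row per measure with baseline/slope estimates, CIs,
    p-values, R2m/R2c and the percent of participants with >= 10% relative
    conditional-mean change over 6 months in the population direction.
    """
    daily = daily.copy()
    daily["date"] = pd.to_datetime(daily["date"])
    base = daily.groupby("participant_id")["date"].transform("min")
    daily["t_months"] = (daily["date"] - base).dt.days / 30.4375
    rows = []
    for measure, sub in daily.groupby("measure"):
        if measures is not None and measure not in measures:
            continue
        sub = sub.dropna(subset=["value"])
        if sub.empty or sub["participant_id"].nunique() < 2:
            continue
        fit = ProgressionModel(sub, "value").fit()
        r2m, r2c = fit.r2() if fit.converged else (float("nan"),) * 2
        rows.append(
            {
                "measure": measure,
                "device": sub["device"].iloc[0],
                "baseline_est": fit.params["Intercept"],
                "baseline_ci_low": fit.conf_int.loc["Intercept", "ci_low"],
                "baseline_ci_high": fit.conf_int.loc["Intercept", "ci_high"],
                "slope_est": fit.params["t_months"],
                "slope_ci_low": fit.conf_int.loc["t_months", "ci_low"],
                "slope_ci_high": fit.conf_int.loc["t_months", "ci_high"],
                "slope_p": fit.pvalues["t_months"],
                "r2m": r2m,
                "r2c": r2c,
                "pct_rel_change_6m": fit.pct_relative_change()
                if fit.converged
                else float("nan"),
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)
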