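"""Monitoring-frequency sensitivity analysis.

Re-estimates the total-activity-counts trajectory under reduced data
collection schedules: cyclic patterns of wD weeks of data followed by wB
weeks of break, anchored at each participant's baseline day, versus the
all-data fit. The nine study schedules are "all", 2wD with 2/4/6/8wB, and
1wD with 2/4/6/8wB.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ProgressionModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Scenario:
    weeks_data: int
    weeks_break: int

    def __post_init__(self) -> None:
        if self.weeks_data < 1:
            raise ValueError("weeks_data must be >= 1")
        if self.weeks_break < 0:
            raise ValueError("weeks_break must be >= 0")

    @property
    def label(self) -> str:
        if self.weeks_break == 0:
            return "all"
        return f"{self.weeks_data}wD + {self.weeks_break}wB"


def default_scenarios() -> list[Scenario]:
    out = [Scenario(1, 0)]  # "all"
    for wd in (2, 1):
        for wb in (2, 4, 6, 8):
            out.append(Scenario(wd, wb))
    return out


def scenario_mask(day_indices: np.ndarray, scenario: Scenario) -> np.ndarray:
    """True for retained days: the first wD weeks of each wD+wB-week cycle.

    Day indices count from the participant's baseline day (0-based).
    """
    days = np.asarray(day_indices, dtype=int)
    if scenario.weeks_break == 0:
        return np.ones(days.shape, dtype=bool)
    cycle = 7 * (scenario.weeks_data + scenario.weeks_break)
    return (days % cycle) < 7 * scenario.weeks_data


def run_sensitivity(
    daily: pd.DataFrame,
    scenarios: list[Scenario] | None = None,
    value_col: str = "value",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fit value ~ time (random intercept + slope) under each scenario.

    `daily` needs columns participant_id, day_index, t_months and the value
    column (one measure, valid days only). Returns per scenario the baseline
    and monthly-change estimates, their percent deviation from the all-data
    fit, and the slope's significance flag. Participants left with fewer
    than 2 days under a scenario are dropped (logged).
    """
    if scenarios is None:
        scenarios = default_scenarios()
    daily = daily.dropna(subset=[value_col])
    rows = []
    ref = None
    for sc in scenarios:
        keep = scenario_mask(daily["day_index"].to_numpy(), sc)
        sub = daily[keep]
        sizes = sub.groupby("participant_id").size()
        ok = sizes.index[sizes >= 2]
        dropped = sizes.index.difference(ok).tolist() + [
            p
            for p in daily["participant_id"].unique()
            if p not in sizes.index
        ]
        if dropped:
            logger.warning(
                "scenario %s: dropping %d participants with <2 days",
                sc.label, len(dropped),
            )
        sub = sub[sub["participant_id"].isin(ok)]
        fit = ProgressionModel(sub, value_col).fit()
        baseline = fit.params["Intercept"]
        slope = fit.params[fit.model.time]
        if ref is None:
            ref = (baseline, slope)
        rows.append(
            {
                "scenario": sc.label,
                "n_days": len(sub),
                "n_participants": sub["participant_id"].nunique(),
                "baseline_est": baseline,
                "slope_est": slope,
                "baseline_pct_deviation": 100.0
                * abs(baseline - ref[0])
                / abs(ref[0]),
                "slope_pct_deviation": 100.0 * abs(slope - ref[1]) / abs(ref[1]),
                "slope_p": fit.pvalues[fit.model.time],
                "slope_significant": bool(
                    fit.pvalues[fit.model.time] < alpha
                ),
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)
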