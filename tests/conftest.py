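"""Shared fixtures: small crafted grids and a compact synthetic cohort."""

from __future__ import annotations

from datetime import date

import numpy as np
import pytest

from alswear import ACTIGRAPH, MODUS, CohortConfig, ImputedDayGrid, MinuteDayGrid
from alswear.config import MissingnessParams, RandomEffects

N = 1440


def make_actigraph_day(
    values=0.0, wear=True, missing=False, pid="P001", day=date(2021, 1, 4)
) -> MinuteDayGrid:
    v = np.full(N, float(values)) if np.isscalar(values) else np.asarray(values, float)
    w = np.full(N, wear) if np.isscalar(wear) else np.asarray(wear, bool)
    m = np.full(N, missing) if np.isscalar(missing) else np.asarray(missing, bool)
    v = v.copy()
    v[m] = np.nan
    return MinuteDayGrid(pid, day, ACTIGRAPH, v, m, wear=w)


def make_modus_day(values=0.0, pid="P002", day=date(2021, 1, 4)) -> MinuteDayGrid:
    v = np.full(N, float(values)) if np.isscalar(values) else np.asarray(values, float)
    return MinuteDayGrid(pid, day, MODUS, v, np.zeros(N, bool))


def make_imputed_day(values, pid="P001", day=date(2021, 1, 4)) -> ImputedDayGrid:
    v = np.full(N, float(values)) if np.isscalar(values) else np.asarray(values, float)
    return ImputedDayGrid(
        pid, day, ACTIGRAPH, v, np.zeros(N, bool),
        wear=np.ones(N, bool), imputed=np.zeros(N, bool),
    )


def noiseless_config(**overrides) -> CohortConfig:
    """All random-effect / residual / latent SDs zero; no missingness."""
    cfg = CohortConfig(**overrides)
    cfg.surveys.alsfrs_re = RandomEffects(0.0, 0.0)
    cfg.surveys.roads_re = RandomEffects(0.0, 0.0)
    cfg.surveys.alsfrs_r_residual_sd = 0.0
    cfg.surveys.alsfrs_rse_residual_sd = 0.0
    cfg.surveys.roads_residual_sd = 0.0
    cfg.latent_intercept_sd = 0.0
    cfg.latent_slope_sd = 0.0
    for act in (cfg.actigraph_activity, cfg.modus_activity):
        act.re = RandomEffects(0.0, 0.0)
        act.residual_sd = 0.0
    cfg.missingness = MissingnessParams(
        nonwear_blocks_mean=0.0, charging_gap_prob=0.0
    )
    cfg.survey_completion_prob = 1.0
    cfg.surveys.round_scores = False
    return cfg


@pytest.fixture(scope="session")
def small_cohort():
    """8 participants, 30 days, minute level: fast full-pipeline material."""
    from alswear import generate_cohort

    cfg = CohortConfig(n_participants=8, observation_days=30, master_seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort_daily():
    """Default-size cohort at daily resolution (no minute expansion)."""
    from alswear import generate_cohort

    return generate_cohort(CohortConfig(master_seed=5), minute_level=False)
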