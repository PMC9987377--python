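"""Generator contracts: determinism, configured moments, coupling, schedules."""

import numpy as np
import pandas as pd
import pytest

from alswear import (
    ACTIGRAPH,
    ALSFRS_R,
    ALSFRS_RSE,
    DAYS_PER_MONTH,
    MODUS,
    ROADS,
    CohortConfig,
    cohort_checksum,
    generate_cohort,
    generate_minute_day,
)
from alswear.config import MissingnessParams
from alswear.simulate import (
    _participant_rng,
    generate_profile,
    staff_visit_days,
    survey_schedule,
)

from conftest import noiseless_config


def test_default_cohort_shape():
    cohort = generate_cohort(CohortConfig(master_seed=1), minute_level=False)
    devices = cohort.truth["device"].value_counts()
    assert devices[ACTIGRAPH] == 20 and devices[MODUS] == 20
    assert len(cohort.profiles) == 40
    assert set(cohort.surveys["instrument"]) == {ALSFRS_R, ALSFRS_RSE, ROADS}


def test_same_seed_is_byte_identical():
    cfg = CohortConfig(n_participants=4, observation_days=10, master_seed=3)
    a = generate_cohort(cfg)
    b = generate_cohort(cfg)
    assert cohort_checksum(a) == cohort_checksum(b)


def test_different_seed_differs():
    kw = dict(n_participants=4, observation_days=10)
    a = generate_cohort(CohortConfig(master_seed=3, **kw))
    b = generate_cohort(CohortConfig(master_seed=4, **kw))
    assert cohort_checksum(a) != cohort_checksum(b)


def test_adding_participant_preserves_existing_streams():
    a = generate_cohort(
        CohortConfig(n_participants=4, observation_days=5, master_seed=9)
    )
    b = generate_cohort(
        CohortConfig(n_participants=5, observation_days=5, master_seed=9)
    )
    pa = a.surveys[a.surveys["participant_id"].isin(["P001", "P002"])]
    pb = b.surveys[b.surveys["participant_id"].isin(["P001", "P002"])]
    pd.testing.assert_frame_equal(
        pa.reset_index(drop=True), pb.reset_index(drop=True)
    )


def test_noiseless_surveys_follow_configured_lines_exactly():
    cfg = noiseless_config(n_participants=4, observation_days=180, master_seed=2)
    cohort = generate_cohort(cfg, minute_level=False)
    for inst, b0, b1 in [
        (ALSFRS_RSE, 31.6 + 2.86, -0.48),
        (ROADS, 84.9, -1.26),
        (ALSFRS_R, 31.6, -0.37),
    ]:
        sub = cohort.surveys[cohort.surveys["instrument"] == inst]
        expected = b0 + b1 * sub["t_months"]
        np.testing.assert_allclose(sub["score"], expected)


def test_offset_applies_only_to_self_entry_alsfrs():
    cfg = noiseless_config(n_participants=2, master_seed=0)
    cohort = generate_cohort(cfg, minute_level=False)
    base = cohort.surveys[cohort.surveys["t_months"] == 0]
    rse = base[base["instrument"] == ALSFRS_RSE]["score"].iloc[0]
    staff = base[base["instrument"] == ALSFRS_R]["score"].iloc[0]
    roads = base[base["instrument"] == ROADS]["score"].iloc[0]
    assert rse - staff == pytest.approx(2.86)
    assert roads == pytest.approx(84.9)


def test_scores_clipped_to_admissible_range():
    cfg = noiseless_config(n_participants=2, master_seed=0)
    cfg.surveys.alsfrs_r_baseline = 3.0
    cfg.surveys.alsfrs_r_slope = -2.0  # crosses zero within 6 months
    cohort = generate_cohort(cfg, minute_level=False)
    scores = cohort.surveys[cohort.surveys["instrument"] == ALSFRS_R]["score"]
    assert scores.min() == 0.0
    assert (scores >= 0).all()


def test_survey_schedule_respects_interval_and_staff_months():
    cfg = CohortConfig(master_seed=6)
    rng = _participant_rng(cfg.master_seed, 0)
    days = survey_schedule(cfg, rng)
    gaps = np.diff(days)
    assert days[0] == 0
    assert ((gaps >= 14) & (gaps <= 28)).all()
    assert staff_visit_days(cfg) == [0, 91, 179]


def test_flat_noiseless_activity_gives_identical_daily_totals():
    cfg = noiseless_config(n_participants=2, observation_days=5, master_seed=1)
    cfg.actigraph_activity.slope = 0.0
    rng = _participant_rng(cfg.master_seed, 0)
    profile = generate_profile(cfg, 0, ACTIGRAPH, rng)
    totals = {
        np.nansum(generate_minute_day(cfg, profile, d, rng).values)
        for d in range(5)
    }
    assert len(totals) == 1
    assert totals.pop() == pytest.approx(cfg.actigraph_activity.baseline, abs=1)


def test_forced_charging_gap_yields_exactly_240_missing_minutes():
    cfg = noiseless_config(n_participants=2, master_seed=8)
    cfg.missingness = MissingnessParams(
        nonwear_blocks_mean=0.0, charging_gap_prob=1.0, charging_gap_minutes=240
    )
    rng = _participant_rng(cfg.master_seed, 0)
    profile = generate_profile(cfg, 0, ACTIGRAPH, rng)
    grid = generate_minute_day(cfg, profile, 0, rng)
    assert int(grid.missing.sum()) == 240
    assert np.isnan(grid.values[grid.missing]).all()


def test_minute_values_nonnegative_and_sum_matches_daily_truth(small_cohort):
    for g in small_cohort.grids[:200]:
        vals = np.nan_to_num(g.values, nan=0.0)
        assert (vals >= 0).all()
    # ankle days have no non-wear erasure, so sums equal the rounded truth
    modus = [g for g in small_cohort.grids if g.device == MODUS][:50]
    truth_df = small_cohort.daily_truth
    for g in modus:
        row = truth_df[
            (truth_df["participant_id"] == g.participant_id)
            & (truth_df["date"] == g.date)
        ]
        assert np.nansum(g.values) == pytest.approx(
            round(row["true_total"].iloc[0]), abs=0.5
        )


def test_monte_carlo_daily_mean_matches_configured_baseline():
    """1000 simulated flat-trajectory days: empirical mean within 3 MC SEs."""
    cfg = CohortConfig(n_participants=2, observation_days=1, master_seed=13)
    cfg.actigraph_activity.slope = 0.0
    cfg.actigraph_activity.re.intercept_sd = 0.0
    cfg.actigraph_activity.re.slope_sd = 0.0
    cfg.latent_intercept_sd = 0.0
    cfg.latent_slope_sd = 0.0
    cfg.missingness = MissingnessParams(
        nonwear_blocks_mean=0.0, charging_gap_prob=0.0
    )
    rng = _participant_rng(cfg.master_seed, 0)
    profile = generate_profile(cfg, 0, ACTIGRAPH, rng)
    sums = np.array(
        [
            np.nansum(generate_minute_day(cfg, profile, 0, rng).values)
            for _ in range(1000)
        ]
    )
    se = sums.std(ddof=1) / np.sqrt(len(sums))
    assert abs(sums.mean() - cfg.actigraph_activity.baseline) < 3 * se


def test_empirical_survey_moments_match_truth_at_n500():
    """Per-participant OLS baselines/slopes recover configured moments."""
    cfg = CohortConfig(
        n_participants=500, observation_days=180, master_seed=21
    )
    cohort = generate_cohort(cfg, minute_level=False)
    sub = cohort.surveys[cohort.surveys["instrument"] == ROADS]
    coefs = []
    for _, df in sub.groupby("participant_id"):
        if len(df) < 3:
            continue
        b1, b0 = np.polyfit(df["t_months"], df["score"], 1)
        coefs.append((b0, b1))
    b0s, b1s = np.array(coefs).T
    se0 = b0s.std(ddof=1) / np.sqrt(len(b0s))
    se1 = b1s.std(ddof=1) / np.sqrt(len(b1s))
    assert abs(b0s.mean() - 84.9) < 3 * se0
    assert abs(b1s.mean() - (-1.26)) < 3 * se1


def test_latent_coupling_links_activity_and_survey_slopes():
    """Positive coupling => per-participant activity and survey slopes correlate."""
    cfg = CohortConfig(n_participants=500, master_seed=17)
    cohort = generate_cohort(cfg, minute_level=False)
    truth = cohort.truth
    slopes_act = truth["activity_slope_total"]
    # survey slope = configured slope + alsfrs b1 + loading * latent slope
    slopes_survey = (
        truth["alsfrs_b1"] + cfg.surveys.alsfrs_latent_loading * truth["latent_slope"]
    )
    r = np.corrcoef(slopes_act, slopes_survey)[0, 1]
    assert r > 0.2
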