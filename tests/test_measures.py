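"""Daily-measure operations against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest

from alswear import ACTIGRAPH_MEASURES, MODUS_MEASURES, derive_all
from alswear.measures import (
    active_sedentary_minutes,
    cadence_statistics,
    log_total_activity_counts,
    max_consecutive_cadence,
    modus_daily_steps,
    peak_performance_index,
    percent_time_bands,
    total_activity_counts,
    total_log_activity_counts,
    transition_probabilities,
)
from alswear.validity import day_validity

from conftest import make_imputed_day, make_modus_day
from oracles import (
    oracle_active_sedentary,
    oracle_max_window_mean,
    oracle_percentile_linear,
    oracle_sum,
    oracle_top_k_mean,
    oracle_total_log,
    oracle_transitions,
)


class TestActivityCountSums:
    def test_all_zero(self):
        day = make_imputed_day(0.0)
        assert total_activity_counts(day) == 0
        assert log_total_activity_counts(day) == 0
        assert total_log_activity_counts(day) == 0

    def test_constant_day(self):
        assert total_activity_counts(make_imputed_day(100.0)) == 144_000

    def test_ramp_day_matches_closed_form(self):
        day = make_imputed_day(np.arange(1440, dtype=float))
        assert total_activity_counts(day) == 1439 * 1440 / 2 == 1_036_080

    def test_single_minute_e_minus_one(self):
        v = np.zeros(1440)
        v[0] = math.e - 1
        day = make_imputed_day(v)
        assert log_total_activity_counts(day) == pytest.approx(1.0)
        assert total_log_activity_counts(day) == pytest.approx(1.0)

    def test_total_log_bound_and_exact_sum(self):
        rng = np.random.default_rng(3)
        v = rng.integers(0, 5000, 1440).astype(float)
        day = make_imputed_day(v)
        tl = total_log_activity_counts(day)
        assert tl <= 1440 * math.log(v.max() + 1)
        assert tl == pytest.approx(oracle_total_log(v))


class TestActiveSedentary:
    def test_threshold_is_strict(self):
        active, sedentary = active_sedentary_minutes(make_imputed_day(1853.0))
        assert (active, sedentary) == (0, 1440)

    def test_thirty_active_minutes(self):
        v = np.zeros(1440)
        v[:30] = 2000.0
        assert active_sedentary_minutes(make_imputed_day(v)) == (30, 1410)

    def test_partition_identity_random(self):
        rng = np.random.default_rng(7)
        v = rng.integers(0, 4000, 1440).astype(float)
        active, sedentary = active_sedentary_minutes(make_imputed_day(v))
        assert active + sedentary == 1440


class TestTransitionProbabilities:
    def test_toy_sequence(self):
        # labels A,A,S,A,S then all sedentary: check on the 5-minute prefix
        from alswear.measures import _transitions_from_labels

        labels = np.array([True, True, False, True, False])
        astp, satp = _transitions_from_labels(labels)
        assert astp == pytest.approx(2 / 3)
        assert satp == pytest.approx(1.0)

    def test_all_active_day(self):
        astp, satp = transition_probabilities(make_imputed_day(3000.0))
        assert astp == 0.0
        assert math.isnan(satp)

    def test_alternating_day(self):
        v = np.zeros(1440)
        v[::2] = 3000.0
        astp, satp = transition_probabilities(make_imputed_day(v))
        assert astp == 1.0
        assert satp == 1.0


class TestCadence:
    def test_three_stepping_minutes(self):
        v = np.zeros(1440)
        v[[100, 200, 300]] = [10, 20, 30]
        mean, median, p95 = cadence_statistics(make_modus_day(v))
        assert mean == 20 and median == 20

    def test_single_stepping_minute(self):
        v = np.zeros(1440)
        v[10] = 7
        assert cadence_statistics(make_modus_day(v)) == (7, 7, 7)

    def test_no_steps_gives_nan(self):
        assert all(math.isnan(x) for x in cadence_statistics(make_modus_day(0.0)))

    def test_p95_matches_order_statistic_oracle(self):
        rng = np.random.default_rng(11)
        v = np.zeros(1440)
        idx = rng.choice(1440, 100, replace=False)
        v[idx] = rng.integers(1, 120, 100)
        _, _, p95 = cadence_statistics(make_modus_day(v))
        stepping = v[v >= 1]
        assert p95 == pytest.approx(oracle_percentile_linear(stepping, 95))


class TestPercentBands:
    def test_all_low(self):
        v = np.zeros(1440)
        v[: 8 * 60] = 10  # 8 fully stepping hours
        day = make_modus_day(v)
        low, med, high = percent_time_bands(day, day_validity(day))
        assert (low, med, high) == (100.0, 0.0, 0.0)

    def test_band_edges_inclusive(self):
        v = np.zeros(1440)
        v[: 8 * 60] = 1  # make 8 hours valid
        v[0], v[1] = 15, 16
        day = make_modus_day(v)
        low, med, _ = percent_time_bands(day, day_validity(day))
        denom = 480
        assert low == pytest.approx(100 * 479 / denom)
        assert med == pytest.approx(100 * 1 / denom)

    def test_ten_percent_low(self):
        v = np.zeros(1440)
        v[:48] = 5  # 48 low-band minutes in hour 0
        for h in range(1, 8):  # high-band markers keep hours 1-7 valid
            v[h * 60] = 50
        day = make_modus_day(v)
        low, _, _ = percent_time_bands(day, day_validity(day))
        assert low == pytest.approx(100 * 48 / 480) == 10.0

    def test_zero_denominator_gives_nan(self):
        day = make_modus_day(0.0)
        assert all(
            math.isnan(x) for x in percent_time_bands(day, day_validity(day))
        )


class TestMaxCadenceAndPPI:
    def test_window_one_is_max_minute(self):
        v = np.zeros(1440)
        v[7] = 55
        assert max_consecutive_cadence(make_modus_day(v), 1) == 55

    def test_five_consecutive_minutes(self):
        v = np.zeros(1440)
        v[100:105] = 60
        assert max_consecutive_cadence(make_modus_day(v), 5) == 60

    def test_window_20_matches_sliding_oracle(self):
        rng = np.random.default_rng(23)
        v = rng.poisson(2, 1440).astype(float)
        day = make_modus_day(v)
        assert max_consecutive_cadence(day, 20) == pytest.approx(
            oracle_max_window_mean(list(v), 20)
        )

    def test_ppi_top30(self):
        v = np.zeros(1440)
        v[:30] = 60
        assert peak_performance_index(make_modus_day(v)) == 60

    def test_ppi_mixed_values(self):
        v = np.zeros(1440)
        v[0] = 100
        v[1:30] = 50
        expected = (100 + 29 * 50) / 30
        assert peak_performance_index(make_modus_day(v)) == pytest.approx(
            expected
        )
        assert expected == pytest.approx(51.6666, abs=1e-3)

    def test_ppi_all_zero(self):
        assert peak_performance_index(make_modus_day(0.0)) == 0.0

    def test_max_cadence_ordering_random(self):
        rng = np.random.default_rng(5)
        v = rng.poisson(1.5, 1440).astype(float)
        day = make_modus_day(v)
        maxes = [max_consecutive_cadence(day, w) for w in (1, 5, 20, 60)]
        assert maxes == sorted(maxes, reverse=True)

    def test_ppi_at_least_daily_mean(self):
        rng = np.random.default_rng(6)
        v = rng.poisson(2.0, 1440).astype(float)
        day = make_modus_day(v)
        assert peak_performance_index(day) >= v.mean()


class TestDeriveAll:
    def test_row_counts(self):
        ag = [make_imputed_day(100.0), make_imputed_day(200.0)]
        table = derive_all(ag, [])
        assert len(table) == 2 * len(ACTIGRAPH_MEASURES) == 14

    def test_empty_inputs(self):
        assert derive_all([], []).empty

    def test_mixed_cohort_counts(self):
        ag = [make_imputed_day(100.0)]
        md = [make_modus_day(1.0, pid="P002")]
        table = derive_all(ag, md)
        assert len(table) == len(ACTIGRAPH_MEASURES) + len(MODUS_MEASURES)
        assert set(table["measure"]) == set(ACTIGRAPH_MEASURES) | set(
            MODUS_MEASURES
        )


def test_all_operations_agree_with_oracles_on_random_grids():
    """200 random small grids, every operation vs its brute-force oracle."""
    rng = np.random.default_rng(99)
    for _ in range(200):
        ac = rng.integers(0, 4000, 1440).astype(float)
        ag = make_imputed_day(ac)
        assert total_activity_counts(ag) == pytest.approx(oracle_sum(ac))
        assert total_log_activity_counts(ag) == pytest.approx(
            oracle_total_log(ac)
        )
        assert active_sedentary_minutes(ag) == oracle_active_sedentary(
            ac, 1853
        )
        astp, satp = transition_probabilities(ag)
        o_astp, o_satp = oracle_transitions(ac > 1853)
        assert astp == pytest.approx(o_astp, nan_ok=True)
        assert satp == pytest.approx(o_satp, nan_ok=True)

        steps = rng.poisson(1.0, 1440).astype(float)
        md = make_modus_day(steps)
        assert modus_daily_steps(md) == pytest.approx(oracle_sum(steps))
        w = int(rng.choice([1, 5, 20, 60]))
        assert max_consecutive_cadence(md, w) == pytest.approx(
            oracle_max_window_mean(list(steps), w)
        )
        assert peak_performance_index(md) == pytest.approx(
            oracle_top_k_mean(list(steps), 30)
        )
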