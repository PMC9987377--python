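"""Valid-hour / valid-day classification and compliance aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alswear import (
    DataIntegrityError,
    actigraph_valid_hours,
    compliance_summary,
    filter_valid_days,
    modus_valid_hours,
)

from conftest import make_actigraph_day, make_modus_day
from oracles import oracle_valid_hours_actigraph, oracle_valid_hours_modus


class TestActigraphHours:
    def test_fully_worn_day_has_24_valid_hours(self):
        v = actigraph_valid_hours(make_actigraph_day(values=10.0))
        assert v.valid_hour_count == 24
        assert v.is_valid_day

    def test_one_missing_minute_invalidates_its_hour(self):
        missing = np.zeros(1440, bool)
        missing[10 * 60 + 30] = True
        v = actigraph_valid_hours(make_actigraph_day(missing=missing))
        assert v.valid_hour_count == 23
        assert not v.valid_hour_flags[10]

    def test_one_nonwear_minute_invalidates_its_hour(self):
        wear = np.ones(1440, bool)
        wear[59] = False
        v = actigraph_valid_hours(make_actigraph_day(wear=wear))
        assert v.valid_hour_count == 23
        assert not v.valid_hour_flags[0]

    def test_exactly_eight_valid_hours_is_a_valid_day(self):
        wear = np.zeros(1440, bool)
        wear[: 8 * 60] = True
        v = actigraph_valid_hours(make_actigraph_day(wear=wear))
        assert v.valid_hour_count == 8
        assert v.is_valid_day

    def test_seven_valid_hours_is_not_a_valid_day(self):
        wear = np.zeros(1440, bool)
        wear[: 7 * 60] = True
        v = actigraph_valid_hours(make_actigraph_day(wear=wear))
        assert not v.is_valid_day


class TestModusHours:
    def test_single_step_yields_one_valid_hour(self):
        values = np.zeros(1440)
        values[0] = 1
        v = modus_valid_hours(make_modus_day(values))
        assert v.valid_hour_count == 1
        assert not v.is_valid_day

    def test_step_in_each_of_eight_hours_is_valid_day(self):
        values = np.zeros(1440)
        for h in range(8):
            values[h * 60 + 5] = 1
        v = modus_valid_hours(make_modus_day(values))
        assert v.valid_hour_count == 8
        assert v.is_valid_day

    def test_all_zero_day_has_no_valid_hour(self):
        v = modus_valid_hours(make_modus_day(0.0))
        assert v.valid_hour_count == 0


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.data())
def test_valid_hour_counts_match_brute_force(data):
    rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
    wear = rng.random(1440) < 0.9
    missing = rng.random(1440) < 0.05
    ag = make_actigraph_day(values=0.0, wear=wear, missing=missing)
    assert actigraph_valid_hours(ag).valid_hour_count == (
        oracle_valid_hours_actigraph(wear, missing)
    )
    steps = rng.poisson(0.05, 1440).astype(float)
    md = make_modus_day(steps)
    assert modus_valid_hours(md).valid_hour_count == oracle_valid_hours_modus(
        steps
    )


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(0, 1439))
def test_adding_a_worn_minute_never_decreases_valid_hours(seed, idx):
    rng = np.random.default_rng(seed)
    wear = rng.random(1440) < 0.5
    before = actigraph_valid_hours(make_actigraph_day(wear=wear)).valid_hour_count
    wear2 = wear.copy()
    wear2[idx] = True
    after = actigraph_valid_hours(make_actigraph_day(wear=wear2)).valid_hour_count
    assert after >= before


class TestFilterAndCompliance:
    def test_filter_counts_and_table_coverage(self):
        grids = []
        for d in range(10):
            wear = np.zeros(1440, bool)
            hours = 5 if d < 3 else 12  # 3 invalid days
            wear[: hours * 60] = True
            grids.append(
                make_actigraph_day(
                    wear=wear, day=pd.Timestamp("2021-01-01").date()
                    + pd.Timedelta(days=d)
                )
            )
        kept, table = filter_valid_days(grids)
        assert len(kept) == 7
        assert len(table) == 10
        assert table["is_valid_day"].sum() == 7

    def test_empty_input_gives_empty_output(self):
        kept, table = filter_valid_days([])
        assert kept == [] and table.empty

    def test_all_valid_is_identity(self):
        grids = [make_actigraph_day(values=1.0)]
        kept, _ = filter_valid_days(grids)
        assert kept == grids

    def test_mixed_devices_for_one_participant_rejected(self):
        grids = [
            make_actigraph_day(pid="P001"),
            make_modus_day(pid="P001"),
        ]
        with pytest.raises(DataIntegrityError, match="mixed device"):
            filter_valid_days(grids)

    def test_compliance_median_and_range(self):
        # three participants with submission counts {2, 5, 9}
        grids, surveys = [], []
        for pid, n_sub in [("P001", 2), ("P002", 5), ("P003", 9)]:
            grids.append(make_actigraph_day(values=1.0, pid=pid))
            for k in range(n_sub):
                surveys.append(
                    {
                        "participant_id": pid,
                        "date": pd.Timestamp("2021-01-01")
                        + pd.Timedelta(days=14 * k),
                        "instrument": "ALSFRS_RSE",
                        "score": 30.0,
                        "t_months": k,
                    }
                )
        _, validity = filter_valid_days(grids)
        summary = compliance_summary(validity, pd.DataFrame(surveys))
        row = summary[
            (summary["metric"] == "ALSFRS-RSE submissions")
            & (summary["group"] == "combined")
        ].iloc[0]
        assert (row["median"], row["min"], row["max"]) == (5, 2, 9)

    def test_participant_without_valid_days_has_missing_hours_cell(self):
        wear = np.zeros(1440, bool)
        wear[:60] = True  # 1 valid hour -> invalid day
        grids = [make_actigraph_day(wear=wear, pid="P001")]
        _, validity = filter_valid_days(grids)
        surveys = pd.DataFrame(
            [{"participant_id": "P001", "date": "2021-01-01",
              "instrument": "ALSFRS_RSE", "score": 30.0, "t_months": 0.0}]
        )
        summary = compliance_summary(validity, surveys)
        cell = summary[
            summary["metric"] == "Average valid hours on a valid day"
        ]["median"]
        assert cell.isna().all()
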