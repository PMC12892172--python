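"""Collation rules, readers and the home-range estimator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import occabund as oa
from occabund.data import (
    collate_captures,
    collate_tubes,
    estimate_homerange_diameter,
    validate_capture_summary,
    validate_occupancy_summary,
)


def _cap_rows(rows):
    return pd.DataFrame(
        rows, columns=["individual_id", "plot_id", "year", "month",
                       "session_id", "occasion_index", "captured"])


def _tube_rows(rows):
    df = pd.DataFrame(
        rows, columns=["subplot_id", "plot_id", "year", "check_start_date",
                       "check_end_date", "detected"])
    df["check_start_date"] = pd.to_datetime(df["check_start_date"])
    df["check_end_date"] = pd.to_datetime(df["check_end_date"])
    return df


class TestCollateCaptures:
    def test_single_individual_two_of_six_checks(self):
        rows = [("A", "P1", 2020, 5, "2020-S1", i, int(i in (2, 5)))
                for i in range(1, 7)]
        out = collate_captures(_cap_rows(rows), "short")
        assert out[["M", "n", "t"]].iloc[0].tolist() == [1, 2, 6]

    def test_long_timescale_session_collapse(self):
        # individual seen in 2 of 4 sessions -> M=1, n=2, t=4
        rows = []
        for s, m in zip(range(1, 5), (4, 5, 6, 7)):
            sid = f"2020-S{s}"
            for occ in range(1, 4):
                rows.append(("", "P1", 2020, m, sid, occ, 0))
            if s in (2, 4):  # captured twice within each of two sessions
                rows.append(("A", "P1", 2020, m, sid, 1, 1))
                rows.append(("A", "P1", 2020, m, sid, 2, 1))
        out = collate_captures(_cap_rows(rows), "long")
        assert out[["M", "n", "t"]].iloc[0].tolist() == [1, 2, 4]
        assert out["month"].isna().all()

    def test_zero_capture_period_keeps_scheduled_occasions(self):
        rows = [("", "P1", 2020, 6, "2020-S1", i, 0) for i in range(1, 7)]
        out = collate_captures(_cap_rows(rows), "short")
        assert out[["M", "n", "t"]].iloc[0].tolist() == [0, 0, 6]

    def test_duplicate_rows_collapse_and_offseason_dropped(self):
        rows = [("A", "P1", 2020, 5, "S1", 1, 1),
                ("A", "P1", 2020, 5, "S1", 1, 1),
                ("B", "P1", 2020, 3, "S0", 1, 1)]  # March: outside season
        with pytest.warns(UserWarning, match="outside April-July"):
            out = collate_captures(_cap_rows(rows), "short")
        assert out[["M", "n", "t"]].iloc[0].tolist() == [1, 1, 1]

    def test_already_collated_input_rejected(self, desk_dataset):
        captures, *_ = desk_dataset
        summary = collate_captures(captures, "short")
        with pytest.raises(ValueError, match="already collated"):
            collate_captures(summary, "short")


class TestCollateTubes:
    def test_midpoint_month_assignment(self):
        # Apr-25 .. May-9 has midpoint May-2 -> assigned to May
        raw = _tube_rows([("T1", "P1", 2020, "2020-04-25", "2020-05-09", 1)])
        out = collate_tubes(raw, "short")
        assert out["month"].iloc[0] == 5

    def test_month_boundary_midnight_goes_to_earlier_month(self):
        # midpoint exactly 00:00 June-1 -> May
        raw = _tube_rows([("T1", "P1", 2020, "2020-05-25", "2020-06-08", 0)])
        out = collate_tubes(raw, "short")
        assert out["month"].iloc[0] == 5

    def test_zero_detection_plot(self):
        rows = [(f"T{i}", "P1", 2020, "2020-06-01", "2020-06-14", 0)
                for i in range(1, 33)]
        rows += [(f"T{i}", "P1", 2020, "2020-06-15", "2020-06-28", 0)
                 for i in range(1, 33)]
        out = collate_tubes(_tube_rows(rows), "short")
        assert out[["s", "s_star", "d", "k"]].iloc[0].tolist() == [32, 0, 0, 2]

    def test_direct_counts(self):
        rows = [("T1", "P1", 2020, "2020-06-01", "2020-06-14", 1),
                ("T1", "P1", 2020, "2020-06-15", "2020-06-28", 0),
                ("T2", "P1", 2020, "2020-06-01", "2020-06-14", 1),
                ("T2", "P1", 2020, "2020-06-15", "2020-06-28", 1)]
        out = collate_tubes(_tube_rows(rows), "short")
        assert out[["s", "s_star", "d", "k"]].iloc[0].tolist() == [2, 2, 3, 2]

    def test_reversed_interval_and_missing_subplot_error(self):
        raw = _tube_rows([("T1", "P1", 2020, "2020-06-15", "2020-06-01", 1)])
        with pytest.raises(ValueError, match="end before start"):
            collate_tubes(raw, "short")
        raw2 = _tube_rows([(None, "P1", 2020, "2020-06-01", "2020-06-14", 1)])
        with pytest.raises(ValueError, match="subplot_id"):
            collate_tubes(raw2, "short")

    def test_unequal_check_counts_flagged_in_report(self):
        rows = [("T1", "P1", 2020, f"2020-06-{d:02d}", f"2020-06-{d + 3:02d}", 0)
                for d in (1, 5, 9, 13, 17, 21)]
        rows += [("T2", "P1", 2020, "2020-06-01", "2020-06-04", 0)]
        with pytest.warns(UserWarning):
            out, report = collate_tubes(_tube_rows(rows), "short",
                                        return_report=True)
        assert len(report) >= 1
        assert set(report["subplot_id"]) <= {"T1", "T2"}


class TestTemporalConsistency:
    """Short- and long-timescale collations must agree after merging."""

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_long_equals_merged_short_for_M(self, seed):
        rng = np.random.default_rng(seed)
        rows = []
        inds = [f"I{i}" for i in range(4)]
        for s, m in zip(range(1, 5), (4, 5, 6, 7)):
            sid = f"2020-S{s}"
            for occ in range(1, 4):
                rows.append(("", "P1", 2020, m, sid, occ, 0))
                for ind in inds:
                    if rng.random() < 0.3:
                        rows.append((ind, "P1", 2020, m, sid, occ, 1))
        raw = _cap_rows(rows)
        long = collate_captures(raw, "long")
        short = collate_captures(raw, "short")
        # same unique individuals overall
        caught = raw[raw["individual_id"] != ""]
        assert long["M"].iloc[0] == caught["individual_id"].nunique()
        # long captures = number of (individual, session) pairs with >=1 capture
        pairs = caught.groupby(["individual_id", "session_id"]).size()
        assert long["n"].iloc[0] == len(pairs)
        # short t sums to total scheduled checks
        assert short["t"].sum() == 12

    def test_monthly_detections_sum_to_seasonal(self, desk_dataset):
        _, tubes, _, _ = desk_dataset
        short = collate_tubes(tubes, "short")
        long = collate_tubes(tubes, "long")
        monthly = short.groupby(["plot_id", "year"])["d"].sum()
        for (_, row) in long.iterrows():
            assert monthly[(row["plot_id"], row["year"])] == row["d"]


class TestValidation:
    def test_generated_data_satisfy_invariants(self, desk_dataset):
        captures, tubes, _, _ = desk_dataset
        validate_capture_summary(collate_captures(captures, "short"), "short")
        validate_occupancy_summary(collate_tubes(tubes, "short"), "short")
        validate_capture_summary(collate_captures(captures, "long"), "long")
        validate_occupancy_summary(collate_tubes(tubes, "long"), "long")

    def test_invariant_violations_raise(self):
        bad = pd.DataFrame({"plot_id": ["P1"], "year": [2020], "month": [5],
                            "M": [3], "n": [2], "t": [4]})
        with pytest.raises(ValueError, match="M <= n"):
            validate_capture_summary(bad, "short")


class TestHomeRange:
    def test_two_captures_ten_metres_apart(self):
        raw = _cap_rows([("A", "P1", 2020, 5, "S1", 1, 1),
                         ("A", "P1", 2020, 5, "S1", 2, 1)])
        raw["x_m"] = [0.0, 10.0]
        raw["y_m"] = [0.0, 0.0]
        spec = estimate_homerange_diameter(raw)
        assert spec.mean_d == pytest.approx(10.0)
        assert spec.sd_d == 0.0

    def test_mean_of_individual_maxima(self):
        rows, xs = [], []
        for ind, dist in zip("ABC", (10.0, 12.0, 14.0)):
            rows += [(ind, "P1", 2020, 5, "S1", 1, 1),
                     (ind, "P1", 2020, 5, "S1", 2, 1)]
            xs += [0.0, dist]
        raw = _cap_rows(rows)
        raw["x_m"] = xs
        raw["y_m"] = 0.0
        assert estimate_homerange_diameter(raw).mean_d == pytest.approx(12.0)

    def test_max_pairwise_distance_is_over_all_pairs(self):
        # right triangle (0,0),(3,0),(0,4): hypotenuse 5 is the statistic
        raw = _cap_rows([("A", "P1", 2020, 5, "S1", i, 1) for i in (1, 2, 3)])
        raw["x_m"] = [0.0, 3.0, 0.0]
        raw["y_m"] = [0.0, 0.0, 4.0]
        assert estimate_homerange_diameter(raw).mean_d == pytest.approx(5.0)

    def test_no_eligible_individuals_errors(self):
        raw = _cap_rows([("A", "P1", 2020, 5, "S1", 1, 1)])
        raw["x_m"], raw["y_m"] = 0.0, 0.0
        with pytest.raises(ValueError, match="default"):
            estimate_homerange_diameter(raw)
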