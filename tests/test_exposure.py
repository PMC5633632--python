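"""Rolling-window exposure covariates: examples, oracle equality, properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import matchrisk as mr
from matchrisk.exposure import (
    ExposureError,
    ExposureIndex,
    assign_quartile,
    exposure_hours,
    incidence_rates,
    one_month_fge,
    quartile_breakpoints,
    twelve_month_exposure,
)


def _involvements(rows):
    df = pd.DataFrame(rows, columns=["player_id", "team_id", "match_date", "minutes"])
    df["match_date"] = pd.to_datetime(df["match_date"])
    return df


EVAL = pd.Timestamp("2007-03-01")


class TestTwelveMonth:
    def test_empty_window_is_zero(self):
        inv = _involvements([("A", "T", "2005-01-01", 80.0)])
        assert twelve_month_exposure(inv, "A", EVAL, "count") == 0

    def test_twenty_minute_rule_is_inclusive(self):
        inv = _involvements(
            [("A", "T", "2007-01-06", 19.0), ("A", "T", "2007-01-13", 20.0), ("A", "T", "2007-01-20", 80.0)]
        )
        assert twelve_month_exposure(inv, "A", EVAL, "count") == 2

    def test_fge_mode_sums_all_minutes(self):
        rows = [("A", "T", d, 80.0) for d in pd.date_range("2006-06-01", periods=30, freq="7D")]
        inv = _involvements(rows)
        assert twelve_month_exposure(inv, "A", pd.Timestamp("2007-01-01"), "fge") == pytest.approx(30.0)

    def test_window_is_half_open(self):
        # match exactly 365 days before the evaluation date falls outside
        inv = _involvements(
            [("A", "T", EVAL - pd.Timedelta(days=365), 80.0), ("A", "T", EVAL, 80.0)]
        )
        assert twelve_month_exposure(inv, "A", EVAL, "count") == 1


class TestOneMonth:
    def test_single_full_game(self):
        inv = _involvements([("A", "T", "2007-02-20", 80.0)])
        assert one_month_fge(inv, "A", EVAL) == pytest.approx(1.0)

    def test_mixed_minutes(self):
        inv = _involvements(
            [("A", "T", "2007-02-10", 60.0), ("A", "T", "2007-02-17", 20.0), ("A", "T", "2007-02-24", 80.0)]
        )
        assert one_month_fge(inv, "A", EVAL) == pytest.approx(2.0)

    def test_empty_window(self):
        inv = _involvements([("A", "T", "2006-12-01", 80.0)])
        assert one_month_fge(inv, "A", EVAL) == 0.0


class TestQuartiles:
    def test_uniform_1_to_40(self):
        b = quartile_breakpoints(range(1, 41))
        assert b == pytest.approx((10.75, 20.5, 30.25))

    def test_user_breaks_reproduce_published_bins(self):
        # bins <12, 12-21, 22-28, >28 for integer counts
        q = assign_quartile([5, 11, 12, 21, 22, 28, 29, 40], (12, 22, 29))
        assert list(q) == [1, 1, 2, 2, 3, 3, 4, 4]

    def test_degenerate_and_small_inputs_error(self):
        with pytest.raises(ExposureError):
            quartile_breakpoints([7, 7, 7, 7])
        with pytest.raises(ExposureError):
            quartile_breakpoints([1, 2, 3])


class TestExposureHours:
    def _training(self):
        return pd.DataFrame(
            {"team_id": ["T"], "week_start": [pd.Timestamp("2007-01-01")], "hours": [10.0]}
        )

    def test_empty_interval(self):
        inv = _involvements([("A", "T", "2007-01-03", 80.0)])
        assert exposure_hours("A", "2007-01-03", "2007-01-03", inv, self._training(), team_id="T") == 0.0

    def test_match_plus_full_training_week(self):
        inv = _involvements([("A", "T", "2007-01-03", 80.0)])
        got = exposure_hours("A", "2007-01-01", "2007-01-08", inv, self._training(), team_id="T")
        assert got == pytest.approx(80 / 60 + 10.0)

    def test_half_week_pro_rata(self):
        inv = _involvements([("A", "T", "2006-06-01", 80.0)])  # outside interval
        got = exposure_hours(
            "A", "2007-01-01", pd.Timestamp("2007-01-04 12:00"), inv, self._training(), team_id="T"
        )
        assert got == pytest.approx(10.0 * 3.5 / 7)


class TestIncidence:
    def test_definitional_rates(self):
        inj = pd.DataFrame(
            {
                "player_id": ["A"] * 51,
                "injury_date": [pd.Timestamp("2006-10-01")] * 50 + [pd.Timestamp("2006-11-01")],
                "setting": ["match"] * 50 + ["training"],
            }
        )
        totals = pd.DataFrame(
            {"season": [2006, 2006], "setting": ["match", "training"], "hours": [582.0, 1000.0]}
        )
        out = incidence_rates(inj, totals).set_index("setting")
        assert round(out.loc["match", "mean"], 1) == 85.9
        assert out.loc["training", "mean"] == pytest.approx(1.0)

    def test_zero_injuries_positive_hours(self):
        inj = pd.DataFrame({"player_id": [], "injury_date": pd.Series(dtype="datetime64[ns]"), "setting": []})
        totals = pd.DataFrame({"season": [2006], "setting": ["match"], "hours": [100.0]})
        out = incidence_rates(inj, totals)
        assert out["mean"].iloc[0] == 0.0

    def test_zero_hours_error(self):
        inj = pd.DataFrame(
            {"player_id": ["A"], "injury_date": [pd.Timestamp("2006-10-01")], "setting": ["match"]}
        )
        totals = pd.DataFrame({"season": [2006], "setting": ["match"], "hours": [0.0]})
        with pytest.raises(ExposureError):
            incidence_rates(inj, totals)


minutes_lists = st.lists(
    st.tuples(st.integers(min_value=-400, max_value=10), st.floats(min_value=0, max_value=100)),
    min_size=0,
    max_size=25,
)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(minutes_lists)
def test_brute_force_oracle_and_additivity(entries):
    """A naive loop reproduces every window statistic; FGE is additive."""
    eval_date = pd.Timestamp("2007-03-01")
    rows = [("A", "T", eval_date + pd.Timedelta(days=off), m) for off, m in entries]
    inv = _involvements(rows) if rows else _involvements([("Z", "T", "2000-01-01", 0.0)])

    naive_count = sum(1 for off, m in entries if -365 < off <= 0 and m >= 20)
    naive_fge1 = sum(m for off, m in entries if -30 < off <= 0) / 80.0
    assert twelve_month_exposure(inv, "A", eval_date, "count") == naive_count
    assert one_month_fge(inv, "A", eval_date) == pytest.approx(naive_fge1)

    # additivity: per-part FGE sums to whole-list FGE
    half = len(entries) // 2
    part = lambda sub: sum(m for off, m in sub if -30 < off <= 0) / 80.0
    assert part(entries[:half]) + part(entries[half:]) == pytest.approx(naive_fge1)

    # monotonicity: adding an in-window involvement never decreases exposure
    rows2 = rows + [("A", "T", eval_date, 25.0)]
    inv2 = _involvements(rows2)
    assert twelve_month_exposure(inv2, "A", eval_date, "count") == naive_count + 1
    assert one_month_fge(inv2, "A", eval_date) >= naive_fge1


def test_index_matches_dataframe_functions(small_cohort):
    """The fast per-player index agrees with the reference implementations."""
    idx = ExposureIndex.from_cohort(small_cohort)
    epoch = pd.Timestamp("1970-01-01")
    rng = np.random.default_rng(0)
    pids = rng.choice(small_cohort.players["player_id"].unique(), size=5, replace=False)
    for pid in pids:
        for date in pd.date_range("2006-10-01", "2008-05-01", freq="61D"):
            d = (date - epoch).days
            assert idx.twelve_month_count(pid, d) == twelve_month_exposure(
                small_cohort.matches, pid, date, "count"
            )
            assert idx.one_month_fge(pid, d) == pytest.approx(
                one_month_fge(small_cohort.matches, pid, date)
            )
            got = idx.exposure_hours(pid, d, d + 45)
            want = exposure_hours(
                pid, date, date + pd.Timedelta(days=45),
                small_cohort.matches, small_cohort.training, roster=small_cohort.players,
            )
            assert got == pytest.approx(want)


def test_count_equals_fge_for_full_games_only(small_cohort):
    rows = [("A", "T", d, 80.0) for d in pd.date_range("2006-06-01", periods=12, freq="14D")]
    inv = _involvements(rows)
    eval_date = pd.Timestamp("2007-01-01")
    c = twelve_month_exposure(inv, "A", eval_date, "count")
    f = twelve_month_exposure(inv, "A", eval_date, "fge")
    assert float(c) == pytest.approx(f)
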