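"""Shared fixtures: tiny hand-auditable cohorts and one small simulated cohort."""

import numpy as np
import pandas as pd
import pytest

import matchrisk as mr
from matchrisk.intervals import add_standardized, build_counting_process

FIXED_BREAKS = (12.0, 22.0, 29.0)


def brute_partial_loglik(eta, start, stop, events, ties="efron"):
    """Independent risk-set enumeration oracle for the Cox partial likelihood."""
    eta = np.asarray(eta, dtype=float)
    start = np.asarray(start, dtype=float)
    stop = np.asarray(stop, dtype=float)
    events = np.asarray(events, dtype=bool)
    ll = 0.0
    for t in sorted(set(stop[events])):
        D = np.flatnonzero(events & (stop == t))
        R = np.flatnonzero((start < t) & (stop >= t))
        m = len(D)
        wR = np.exp(eta[R]).sum()
        wD = np.exp(eta[D]).sum()
        ll += float(eta[D].sum())
        if ties == "breslow":
            ll -= m * np.log(wR)
        else:
            for l in range(m):
                ll -= np.log(wR - l / m * wD)
    return float(ll)


@pytest.fixture(scope="session")
def small_cohort():
    """4 teams x 12 players x 2 seasons, default effect structure."""
    return mr.simulate(mr.SimConfig(n_teams=4, players_per_team=12, n_seasons=2), seed=11)


@pytest.fixture(scope="session")
def small_rows(small_cohort):
    """Standardized counting-process rows for the small cohort."""
    rows, report = build_counting_process(small_cohort)
    rows, scales = add_standardized(
        rows, ["age", "height_cm", "mass_kg", "prev_injury_count", "one_month_fge"]
    )
    return rows, report, scales


@pytest.fixture(scope="session")
def small_intervals(small_cohort):
    iv, report = mr.build_intervals(small_cohort)
    return iv, report


def two_injury_cohort():
    """Hand-built: player P1 with two injuries, P2 uninjured; no training."""
    players = pd.DataFrame(
        {
            "player_id": ["P1", "P2"],
            "team_id": ["T1", "T1"],
            "birth_date": pd.to_datetime(["1980-06-15", "1983-02-01"]),
            "height_cm": [185.0, 178.0],
            "mass_kg": [100.0, 88.0],
            "position": ["forward", "back"],
            "entry_date": pd.to_datetime(["2006-09-01", "2006-09-01"]),
            "exit_date": pd.to_datetime(["2007-06-30", "2007-06-30"]),
        }
    )
    dates = pd.date_range("2006-09-02", periods=20, freq="7D")
    match_rows = []
    inj1 = pd.Timestamp("2006-10-14")  # 7th match day
    ret1 = pd.Timestamp("2006-10-28")
    inj2 = pd.Timestamp("2006-12-09")
    ret2 = pd.Timestamp("2006-12-23")
    for d in dates:
        match_rows.append(("P2", "T1", d, 80.0))
        absent = (inj1 < d < ret1) or (inj2 < d < ret2)
        if not absent:
            match_rows.append(("P1", "T1", d, 80.0))
    matches = pd.DataFrame(match_rows, columns=["player_id", "team_id", "match_date", "minutes"])
    training = pd.DataFrame(
        {
            "team_id": pd.Series(dtype=str),
            "week_start": pd.Series(dtype="datetime64[ns]"),
            "hours": pd.Series(dtype=float),
        }
    )
    injuries = pd.DataFrame(
        {
            "player_id": ["P1", "P1"],
            "injury_date": [inj1, inj2],
            "return_date": [ret1, ret2],
            "setting": ["match", "training"],
            "diagnosis_code": pd.array([pd.NA, "KXX"], dtype="string"),
        }
    )
    from matchrisk.cohort import Cohort, validate_cohort

    return validate_cohort(Cohort(players, matches, training, injuries))


@pytest.fixture
def hand_cohort():
    return two_injury_cohort()
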