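"""Rolling-window match-exposure covariates and descriptive exposure stats.

Two workload covariates drive the injury-risk models:

* **12-month match exposure** — the number of matches in which a player was
  involved for at least 20 minutes in the preceding 365 days (accumulated /
  chronic load).  A count is used rather than minutes because the ancillary
  loads of a match involvement (travel, preparation, analysis) scale with
  involvements, not minutes.  A full-game-equivalent (FGE) variant —
  total minutes / 80 over the same window, no 20-minute filter — is
  available as a supplementary mode.
* **1-month match exposure** — FGE accumulated in the preceding 30 days
  (recent / acute load); minutes-based because a 30-day involvement count
  has too little variation.

Windows are half-open: (eval_date − span, eval_date], so exposure earlier
on the evaluation day itself counts.  The ≥20-minute rule is inclusive.

Also here: the exposure-hour denominator used as the survival time axis
(individual match minutes plus the team's group training hours, pro-rated
by day overlap), quartile breakpoints for the chronic-exposure interaction,
and per-1000-hour incidence rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort

TWELVE_MONTH_DAYS = 365
ONE_MONTH_DAYS = 30
FULL_GAME_MINUTES = 80.0
MIN_INVOLVEMENT_MINUTES = 20.0


class ExposureError(ValueError):
    """Raised for unknown ids, degenerate quantiles or undefined rates."""


def _player_matches(involvements: pd.DataFrame, player_id: str) -> pd.DataFrame:
    sub = involvements[involvements["player_id"] == player_id]
    if sub.empty and player_id not in set(involvements["player_id"]):
        # an empty history is fine only if the id could exist; callers that
        # hold a roster should pre-check — here absence of any row is legal
        pass
    return sub


def twelve_month_exposure(
    involvements: pd.DataFrame,
    player_id: str,
    eval_date: pd.Timestamp,
    mode: str = "count",
) -> float:
    """Accumulated match exposure over the preceding 12 months.

    mode="count": number of involvements with minutes >= 20 and match_date
    in (eval_date − 365 d, eval_date].  mode="fge": sum(minutes)/80 over the
    same window with no minimum-minutes filter.
    """
    if mode not in ("count", "fge"):
        raise ValueError(f"unknown mode {mode!r}")
    eval_date = pd.Timestamp(eval_date)
    lo = eval_date - pd.Timedelta(days=TWELVE_MONTH_DAYS)
    sub = _player_matches(involvements, player_id)
    in_win = sub[(sub["match_date"] > lo) & (sub["match_date"] <= eval_date)]
    if mode == "count":
        return float((in_win["minutes"] >= MIN_INVOLVEMENT_MINUTES).sum())
    return float(in_win["minutes"].sum() / FULL_GAME_MINUTES)


def one_month_fge(
    involvements: pd.DataFrame, player_id: str, eval_date: pd.Timestamp
) -> float:
    """Recent match exposure: FGE over the preceding 30 days.

    Sum of minutes over (eval_date − 30 d, eval_date] divided by 80; no
    minimum-minutes filter.
    """
    eval_date = pd.Timestamp(eval_date)
    lo = eval_date - pd.Timedelta(days=ONE_MONTH_DAYS)
    sub = _player_matches(involvements, player_id)
    in_win = sub[(sub["match_date"] > lo) & (sub["match_date"] <= eval_date)]
    return float(in_win["minutes"].sum() / FULL_GAME_MINUTES)


def quartile_breakpoints(values) -> tuple[float, float, float]:
    """25th/50th/75th percentile breakpoints of a chronic-exposure sample.

    Uses linear interpolation between order statistics (the numpy default).
    Bins are Q1 = [min, b1), Q2 = [b1, b2), Q3 = [b2, b3), Q4 = [b3, max].
    Raises on fewer than 4 observations or a degenerate (constant) sample;
    callers may instead supply fixed breakpoints wherever quartiles are
    consumed.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 4:
        raise ExposureError("quartile_breakpoints: fewer than 4 observations")
    if np.unique(arr).size < 2:
        raise ExposureError("quartile_breakpoints: all values identical (degenerate quartiles)")
    b1, b2, b3 = np.percentile(arr, [25.0, 50.0, 75.0])
    return float(b1), float(b2), float(b3)


def assign_quartile(values, breakpoints) -> np.ndarray:
    """Map values to ordinal quartiles 1–4 against three ordered breakpoints."""
    b1, b2, b3 = breakpoints
    arr = np.asarray(values, dtype=float)
    return (1 + (arr >= b1).astype(int) + (arr >= b2) + (arr >= b3)).astype(int)


def exposure_hours(
    player_id: str,
    from_date: pd.Timestamp,
    to_date: pd.Timestamp,
    involvements: pd.DataFrame,
    training: pd.DataFrame,
    roster: pd.DataFrame | None = None,
    team_id: str | None = None,
) -> float:
    """Match plus team-training exposure hours over (from_date, to_date].

    Individual match minutes / 60 over the window, plus the player's team's
    weekly group training hours pro-rated by overlapping days / 7.  The
    team attribution follows the roster span(s) covering each training week
    (pass ``roster`` = players table), or a fixed ``team_id``.
    """
    from_date = pd.Timestamp(from_date)
    to_date = pd.Timestamp(to_date)
    if from_date > to_date:
        raise ValueError("exposure_hours: from_date after to_date")
    if from_date == to_date:
        return 0.0

    sub = _player_matches(involvements, player_id)
    in_win = sub[(sub["match_date"] > from_date) & (sub["match_date"] <= to_date)]
    match_hours = float(in_win["minutes"].sum()) / 60.0

    # roster spans that belong to this player, used to attribute team weeks
    if team_id is not None:
        spans = [(pd.Timestamp.min, pd.Timestamp.max, team_id)]
    elif roster is not None:
        mine = roster[roster["player_id"] == player_id]
        if mine.empty:
            raise ExposureError(f"exposure_hours: unknown player_id {player_id!r}")
        spans = list(zip(mine["entry_date"], mine["exit_date"], mine["team_id"]))
    else:
        raise ValueError("exposure_hours: provide roster or team_id for training attribution")

    train_hours = 0.0
    for entry, exit_, tid in spans:
        lo = max(from_date, entry)
        hi = min(to_date, exit_)
        if lo >= hi:
            continue
        tw = training[training["team_id"] == tid]
        for week_start, hours in zip(tw["week_start"], tw["hours"]):
            week_end = week_start + pd.Timedelta(days=7)
            ov_lo = max(lo, week_start)
            ov_hi = min(hi, week_end)
            days = (ov_hi - ov_lo).days + (ov_hi - ov_lo).seconds / 86400.0
            if days > 0:
                train_hours += hours * days / 7.0
    return match_hours + train_hours


def season_label(dates: pd.Series, season_start_month: int = 7) -> pd.Series:
    """Season of each date: the year in which the season starts (July–June)."""
    d = pd.to_datetime(dates)
    return d.dt.year.where(d.dt.month >= season_start_month, d.dt.year - 1)


def incidence_rates(
    injuries: pd.DataFrame,
    exposure_totals: pd.DataFrame,
    season_start_month: int = 7,
) -> pd.DataFrame:
    """Injuries per 1000 exposure hours, by setting, mean ± SD across seasons.

    ``exposure_totals`` must carry columns season, setting, hours (the
    player-hours at risk in that season/setting).  Returns one row per
    setting with per-season rates, their mean and SD.
    """
    inj = injuries.copy()
    inj["season"] = season_label(inj["injury_date"], season_start_month)
    counts = inj.groupby(["season", "setting"]).size().rename("n_injuries").reset_index()
    merged = exposure_totals.merge(counts, on=["season", "setting"], how="left")
    merged["n_injuries"] = merged["n_injuries"].fillna(0).astype(int)
    if (merged["hours"] <= 0).any():
        raise ExposureError("incidence_rates: zero exposure hours for a season/setting")
    merged["rate_per_1000h"] = merged["n_injuries"] / merged["hours"] * 1000.0
    out = (
        merged.groupby("setting")["rate_per_1000h"]
        .agg(mean="mean", sd=lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0)
        .reset_index()
    )
    return out


def cohort_exposure_totals(cohort: Cohort, season_start_month: int = 7) -> pd.DataFrame:
    """Season × setting player-hours at risk for incidence denominators.

    Match hours: sum of individual involvement minutes / 60.  Training
    hours: weekly group hours × number of rostered players that week
    (group sessions expose the whole squad).
    """
    m = cohort.matches.copy()
    m["season"] = season_label(m["match_date"], season_start_month)
    match_tot = (m.groupby("season")["minutes"].sum() / 60.0).rename("hours").reset_index()
    match_tot["setting"] = "match"

    t = cohort.training.copy()
    squads = cohort.players.groupby("team_id")
    counts = {}
    for tid, grp in squads:
        counts[tid] = grp[["entry_date", "exit_date"]].to_numpy()
    n_active = np.zeros(len(t), dtype=float)
    for i, (tid, ws) in enumerate(zip(t["team_id"], t["week_start"])):
        spans = counts.get(tid)
        if spans is None:
            continue
        n_active[i] = float(((spans[:, 0] <= ws) & (spans[:, 1] >= ws)).sum())
    t["player_hours"] = t["hours"] * n_active
    t["season"] = season_label(t["week_start"], season_start_month)
    train_tot = t.groupby("season")["player_hours"].sum().rename("hours").reset_index()
    train_tot["setting"] = "training"

    return pd.concat([match_tot, train_tot], ignore_index=True)[["season", "setting", "hours"]]


@dataclass
class ExposureIndex:
    """Per-player exposure histories pre-sorted for fast repeated lookups.

    Date arithmetic is done on integer day numbers; the rolling-window
    definitions are identical to the DataFrame functions above (verified
    against them by a brute-force oracle in the test suite).
    """

    match_days: dict  # player_id -> int64 array of match day numbers (sorted)
    match_minutes: dict  # player_id -> float array aligned with match_days
    training_weeks: dict  # team_id -> (int64 array of week_start days, float hours)
    spans: dict  # player_id -> list of (entry_day, exit_day, team_id)

    @classmethod
    def from_cohort(cls, cohort: Cohort) -> "ExposureIndex":
        epoch = pd.Timestamp("1970-01-01")

        def day(s):
            return ((s - epoch).dt.days).to_numpy(dtype=np.int64)

        match_days: dict = {}
        match_minutes: dict = {}
        m = cohort.matches.sort_values("match_date")
        for pid, grp in m.groupby("player_id", sort=False):
            match_days[pid] = day(grp["match_date"])
            match_minutes[pid] = grp["minutes"].to_numpy(dtype=float)

        training_weeks: dict = {}
        tr = cohort.training.sort_values("week_start")
        for tid, grp in tr.groupby("team_id", sort=False):
            training_weeks[tid] = (day(grp["week_start"]), grp["hours"].to_numpy(dtype=float))

        spans: dict = {}
        for pid, grp in cohort.players.groupby("player_id", sort=False):
            spans[pid] = list(
                zip(day(grp["entry_date"]), day(grp["exit_date"]), grp["team_id"])
            )
        return cls(match_days, match_minutes, training_weeks, spans)

    def _window(self, player_id, eval_day: int, span_days: int):
        days = self.match_days.get(player_id)
        if days is None:
            return np.empty(0, dtype=np.int64), np.empty(0)
        lo = np.searchsorted(days, eval_day - span_days, side="right")
        hi = np.searchsorted(days, eval_day, side="right")
        return days[lo:hi], self.match_minutes[player_id][lo:hi]

    def twelve_month_count(self, player_id, eval_day: int) -> int:
        _, mins = self._window(player_id, eval_day, TWELVE_MONTH_DAYS)
        return int((mins >= MIN_INVOLVEMENT_MINUTES).sum())

    def twelve_month_fge(self, player_id, eval_day: int) -> float:
        _, mins = self._window(player_id, eval_day, TWELVE_MONTH_DAYS)
        return float(mins.sum() / FULL_GAME_MINUTES)

    def one_month_fge(self, player_id, eval_day: int) -> float:
        _, mins = self._window(player_id, eval_day, ONE_MONTH_DAYS)
        return float(mins.sum() / FULL_GAME_MINUTES)

    def exposure_hours(self, player_id, from_day: int, to_day: int) -> float:
        """Match + pro-rated team training hours over (from_day, to_day]."""
        if from_day >= to_day:
            return 0.0
        days = self.match_days.get(player_id)
        hours = 0.0
        if days is not None:
            lo = np.searchsorted(days, from_day, side="right")
            hi = np.searchsorted(days, to_day, side="right")
            hours += float(self.match_minutes[player_id][lo:hi].sum()) / 60.0
        for entry, exit_, tid in self.spans.get(player_id, ()):
            lo_d = max(from_day, int(entry))
            hi_d = min(to_day, int(exit_))
            if lo_d >= hi_d or tid not in self.training_weeks:
                continue
            wk_days, wk_hours = self.training_weeks[tid]
            i0 = np.searchsorted(wk_days, lo_d - 6, side="left")
            i1 = np.searchsorted(wk_days, hi_d, side="right")
            for wd, wh in zip(wk_days[i0:i1], wk_hours[i0:i1]):
                ov = min(hi_d, wd + 7) - max(lo_d, int(wd))
                if ov > 0:
                    hours += wh * ov / 7.0
        return hours


def exposure_snapshots(cohort: Cohort, eval_points: pd.DataFrame) -> pd.DataFrame:
    """Evaluate all rolling-exposure covariates at (player_id, eval_date) rows.

    Returns a DataFrame with player_id, eval_date, twelve_month_matches,
    twelve_month_fge, one_month_fge (the optional ``exposures.csv`` payload).
    """
    idx = ExposureIndex.from_cohort(cohort)
    epoch = pd.Timestamp("1970-01-01")
    out = []
    for pid, date in zip(eval_points["player_id"], eval_points["eval_date"]):
        d = (pd.Timestamp(date) - epoch).days
        out.append(
            {
                "player_id": pid,
                "eval_date": pd.Timestamp(date),
                "twelve_month_matches": idx.twelve_month_count(pid, d),
                "twelve_month_fge": idx.twelve_month_fge(pid, d),
                "one_month_fge": idx.one_month_fge(pid, d),
            }
        )
    return pd.DataFrame(out)
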