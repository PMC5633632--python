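"""Recurrent-event gap-time risk intervals.

Each player's follow-up is cut at injuries: interval 1 runs from study entry
to the first injury (event) or to censoring; interval k runs from the return
date of injury k−1 to injury k or censoring.  The survival time axis is the
exposure hours accrued within the interval (individual match minutes plus
pro-rated team training hours) — the gap-time clock restarts at every return
from injury, and a player accrues no risk time while absent injured.

Covariates are evaluated at each interval's end date (the injury or
censoring time point): age, height, mass, position, number of previous
injuries in the dataset, 12-month match-involvement count, 1-month FGE, and
the 12-month exposure quartile.  Intervals whose 12-month match exposure is
zero are excluded from the analysis set (and counted in the build report);
the injury itself still advances the player's previous-injury history.

Zero-duration event intervals (an injury on the return day before any
exposure accrued) are floored at a small positive duration so the event
stays in the risk set rather than being silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, player_spans
from .exposure import ExposureIndex, assign_quartile, quartile_breakpoints

ZERO_DURATION_FLOOR_HOURS = 0.01
DAYS_PER_YEAR = 365.25

INTERVAL_COLUMNS = [
    "player_id",
    "team_id",
    "start_date",
    "end_date",
    "event",
    "duration_hours",
    "age",
    "height_cm",
    "mass_kg",
    "position",
    "prev_injury_count",
    "twelve_month_matches",
    "one_month_fge",
    "twelve_month_quartile",
]


@dataclass
class BuildReport:
    """Bookkeeping from build_intervals: exclusions and quartile scale."""

    n_intervals: int = 0
    n_events: int = 0
    n_excluded_zero_exposure: int = 0
    n_excluded_events: int = 0
    n_zero_duration_floored: int = 0
    n_zero_duration_censored_dropped: int = 0
    quartile_breakpoints: tuple | None = None
    excluded_rows: list = field(default_factory=list)


def build_intervals(
    cohort: Cohort,
    censor_date=None,
    breakpoints: tuple | None = None,
    exclude_zero_twelve_month: bool = True,
) -> tuple[pd.DataFrame, BuildReport]:
    """Build the ordered gap-time risk-interval table for a cohort.

    Parameters
    ----------
    cohort : validated Cohort bundle.
    censor_date : optional global administrative censoring date; each
        player is censored at min(censor_date, player exit date).
    breakpoints : optional fixed three-point breakpoints for the 12-month
        exposure quartiles; derived from the retained intervals' observed
        counts when omitted.
    exclude_zero_twelve_month : drop intervals with a 12-month match
        exposure of zero (the analysis rule); disable for diagnostics.

    Returns (intervals DataFrame, BuildReport).
    """
    idx = ExposureIndex.from_cohort(cohort)
    spans = player_spans(cohort.players)
    epoch = pd.Timestamp("1970-01-01")
    censor_day_global = None
    if censor_date is not None:
        censor_day_global = (pd.Timestamp(censor_date) - epoch).days

    inj_by_player = {
        pid: grp.sort_values("injury_date")
        for pid, grp in cohort.injuries.groupby("player_id", sort=False)
    }

    # team label at a given date follows the roster spans
    roster_rows = {
        pid: list(zip(grp["entry_date"], grp["exit_date"], grp["team_id"]))
        for pid, grp in cohort.players.groupby("player_id", sort=False)
    }

    def team_at(pid, date):
        for entry, exit_, tid in roster_rows[pid]:
            if entry <= date <= exit_:
                return tid
        return roster_rows[pid][-1][2]

    report = BuildReport()
    rows = []
    for pid, prof in spans.iterrows():
        entry = prof["entry_date"]
        exit_ = prof["exit_date"]
        censor = exit_
        if censor_day_global is not None:
            censor = min(censor, epoch + pd.Timedelta(days=censor_day_global))
        injuries = inj_by_player.get(pid)
        cuts = []  # (start, end, event)
        start = entry
        prev_count = 0
        if injuries is not None:
            for _, inj in injuries.iterrows():
                if inj["injury_date"] > censor:
                    break
                if inj["injury_date"] < start:
                    # injury inside an absence spell would have been caught by
                    # validation; injuries before entry are not reconstructed
                    continue
                cuts.append((start, inj["injury_date"], True, prev_count))
                prev_count += 1
                start = inj["return_date"]
                if start >= censor:
                    start = None
                    break
        if start is not None and start < censor:
            cuts.append((start, censor, False, prev_count))

        for start, end, event, n_prev in cuts:
            start_day = (start - epoch).days
            end_day = (end - epoch).days
            dur = idx.exposure_hours(pid, start_day, end_day)
            if dur <= 0.0 and event:
                dur = ZERO_DURATION_FLOOR_HOURS
                report.n_zero_duration_floored += 1
            elif dur <= 0.0:
                # censored with no exposure accrued: at risk for no event
                # time, contributes nothing to any risk set
                report.n_zero_duration_censored_dropped += 1
                continue
            tm = idx.twelve_month_count(pid, end_day)
            row = {
                "player_id": pid,
                "team_id": team_at(pid, end),
                "start_date": start,
                "end_date": end,
                "event": bool(event),
                "duration_hours": float(dur),
                "age": (end - prof["birth_date"]).days / DAYS_PER_YEAR,
                "height_cm": prof["height_cm"],
                "mass_kg": prof["mass_kg"],
                "position": prof["position"],
                "prev_injury_count": int(n_prev),
                "twelve_month_matches": int(tm),
                "one_month_fge": idx.one_month_fge(pid, end_day),
            }
            if exclude_zero_twelve_month and tm == 0:
                report.n_excluded_zero_exposure += 1
                if event:
                    report.n_excluded_events += 1
                report.excluded_rows.append(row)
            else:
                rows.append(row)

    intervals = pd.DataFrame(rows, columns=[c for c in INTERVAL_COLUMNS if c != "twelve_month_quartile"])
    if len(intervals):
        intervals = intervals.sort_values(["player_id", "start_date"]).reset_index(drop=True)
        if breakpoints is None:
            breakpoints = quartile_breakpoints(intervals["twelve_month_matches"])
        intervals["twelve_month_quartile"] = assign_quartile(
            intervals["twelve_month_matches"], breakpoints
        )
    else:
        intervals["twelve_month_quartile"] = pd.Series(dtype=int)

    report.n_intervals = len(intervals)
    report.n_events = int(intervals["event"].sum()) if len(intervals) else 0
    report.quartile_breakpoints = breakpoints
    return intervals, report


COUNTING_COLUMNS = [
    "interval_id",
    "player_id",
    "team_id",
    "seg_start_date",
    "seg_end_date",
    "gap_start_hours",
    "gap_stop_hours",
    "event",
    "age",
    "height_cm",
    "mass_kg",
    "position",
    "prev_injury_count",
    "twelve_month_matches",
    "one_month_fge",
    "twelve_month_quartile",
]

_MONDAY_MOD = 4  # 1970-01-05 (day 4) was a Monday


def _next_monday(day: int) -> int:
    nm = day + (_MONDAY_MOD - day) % 7
    return nm + 7 if nm <= day else nm


class _PlayerHistory:
    """Vectorized per-player rolling-window and exposure-hour lookups."""

    def __init__(self, mdays, mmins, spans, training_weeks):
        self.mdays = mdays
        self.c20 = np.concatenate([[0], np.cumsum(mmins >= 20.0)])
        self.cmin = np.concatenate([[0.0], np.cumsum(mmins)])
        self.spans = spans  # list of (entry_day, exit_day, team_id)
        self.training_weeks = training_weeks  # team -> (week_days, cum_hours incl 0)

    def count12(self, days):
        hi = np.searchsorted(self.mdays, days, side="right")
        lo = np.searchsorted(self.mdays, np.asarray(days) - 365, side="right")
        return (self.c20[hi] - self.c20[lo]).astype(int)

    def fge1(self, days):
        hi = np.searchsorted(self.mdays, days, side="right")
        lo = np.searchsorted(self.mdays, np.asarray(days) - 30, side="right")
        return (self.cmin[hi] - self.cmin[lo]) / 80.0

    def match_hours(self, lo, hi):
        a = np.searchsorted(self.mdays, lo, side="right")
        b = np.searchsorted(self.mdays, hi, side="right")
        return (self.cmin[b] - self.cmin[a]) / 60.0

    def _train_F(self, tid, days):
        """Cumulative pro-rated team training hours up to each day."""
        wk, cumH, hrs = self.training_weeks.get(tid, (None, None, None))
        days = np.asarray(days)
        if wk is None or len(wk) == 0:
            return np.zeros(days.shape)
        full = np.searchsorted(wk, days - 7, side="right")
        pos = np.searchsorted(wk, days, side="left")
        out = cumH[full]
        part = pos - 1
        m = part >= full
        if np.any(m):
            out = out.astype(float)
            out[m] += hrs[part[m]] * (days[m] - wk[part[m]]) / 7.0
        return out

    def train_hours(self, lo, hi):
        lo = np.asarray(lo)
        hi = np.asarray(hi)
        out = np.zeros(lo.shape, dtype=float)
        for entry, exit_, tid in self.spans:
            l = np.clip(lo, entry, exit_)
            h = np.clip(hi, entry, exit_)
            out += self._train_F(tid, h) - self._train_F(tid, l)
        return out


def _player_cuts(cohort: Cohort, censor_date=None):
    """Yield (player_id, profile, [(start, end, event, prev_count), ...])."""
    spans = player_spans(cohort.players)
    epoch = pd.Timestamp("1970-01-01")
    censor_global = pd.Timestamp(censor_date) if censor_date is not None else None
    inj_by_player = {
        pid: grp.sort_values("injury_date")
        for pid, grp in cohort.injuries.groupby("player_id", sort=False)
    }
    for pid, prof in spans.iterrows():
        entry, exit_ = prof["entry_date"], prof["exit_date"]
        censor = exit_ if censor_global is None else min(exit_, censor_global)
        injuries = inj_by_player.get(pid)
        cuts = []
        start, prev_count = entry, 0
        if injuries is not None:
            for _, inj in injuries.iterrows():
                if inj["injury_date"] > censor:
                    break
                if inj["injury_date"] < start:
                    continue  # injuries before entry are not reconstructed
                cuts.append((start, inj["injury_date"], True, prev_count))
                prev_count += 1
                start = inj["return_date"]
                if start >= censor:
                    start = None
                    break
        if start is not None and start < censor:
            cuts.append((start, censor, False, prev_count))
        yield pid, prof, cuts


def build_counting_process(
    cohort: Cohort,
    censor_date=None,
    breakpoints: tuple | None = None,
    exclude_zero_twelve_month: bool = True,
) -> tuple[pd.DataFrame, BuildReport]:
    """Gap-time risk intervals in counting-process (start, stop] form.

    Each risk interval is split at weekly boundaries so the rolling-
    exposure covariates are time-updated for everyone at risk, not only
    for the failing player: a row covers one calendar segment of one
    interval, carries the covariates evaluated at the segment's end date,
    and occupies (gap_start_hours, gap_stop_hours] on the interval's
    exposure-hour clock.  Only the final segment of an interval that ends
    in an injury has event = True.  Segments with no exposure contribute
    no risk time and are omitted (their hours still advance the clock of
    later segments — trivially, by zero).

    The zero-12-month-exposure exclusion applies per segment: a player
    contributes no risk time (and no event) while the preceding 365 days
    contain no >= 20-minute involvement.

    Returns (rows, BuildReport); rows are model-ready for :func:`~matchrisk.frailty.fit`.
    """
    epoch = pd.Timestamp("1970-01-01")

    # per-player histories
    hist: dict = {}
    m = cohort.matches.sort_values("match_date")
    mdays_all = {
        pid: (
            ((grp["match_date"] - epoch).dt.days).to_numpy(dtype=np.int64),
            grp["minutes"].to_numpy(dtype=float),
        )
        for pid, grp in m.groupby("player_id", sort=False)
    }
    tr = cohort.training.sort_values("week_start")
    training_weeks = {}
    for tid, grp in tr.groupby("team_id", sort=False):
        wk = ((grp["week_start"] - epoch).dt.days).to_numpy(dtype=np.int64)
        hrs = grp["hours"].to_numpy(dtype=float)
        training_weeks[tid] = (wk, np.concatenate([[0.0], np.cumsum(hrs)]), hrs)
    span_rows = {
        pid: list(
            zip(
                ((grp["entry_date"] - epoch).dt.days).astype(int),
                ((grp["exit_date"] - epoch).dt.days).astype(int),
                grp["team_id"],
            )
        )
        for pid, grp in cohort.players.groupby("player_id", sort=False)
    }

    report = BuildReport()
    out = {c: [] for c in COUNTING_COLUMNS if c != "twelve_month_quartile"}

    for pid, prof, cuts in _player_cuts(cohort, censor_date):
        mdays, mmins = mdays_all.get(pid, (np.empty(0, dtype=np.int64), np.empty(0)))
        h = _PlayerHistory(mdays, mmins, span_rows[pid], training_weeks)
        birth_day = (prof["birth_date"] - epoch).days
        for k, (start, end, event, n_prev) in enumerate(cuts):
            s = (start - epoch).days
            e = (end - epoch).days
            if e <= s and not event:
                continue
            interior = np.arange(_next_monday(s), e, 7, dtype=np.int64)
            bounds = np.concatenate([[s], interior, [e]])
            lo, hi = bounds[:-1], bounds[1:]
            hours = h.match_hours(lo, hi) + h.train_hours(lo, hi)
            keep = hours > 0.0
            if event:
                keep[-1] = True
                if hours[-1] <= 0.0:
                    hours[-1] = ZERO_DURATION_FLOOR_HOURS
                    report.n_zero_duration_floored += 1
            if not keep.any():
                report.n_zero_duration_censored_dropped += 1
                continue
            stops = np.cumsum(hours)
            starts = stops - hours
            lo, hi, hours = lo[keep], hi[keep], hours[keep]
            starts, stops = starts[keep], stops[keep]
            # rolling covariates are measured with one uniform scheme for
            # cases and comparators: at the segment's match day when the
            # player was involved that week, else midweek.  Anchoring every
            # window the same way keeps the 30-day window's fixture content
            # exchangeable between event rows (which end on injury days,
            # typically match days) and at-risk rows (which end on week
            # boundaries); mixing the two anchors biases the acute-load
            # contrast.
            if len(mdays):
                pos = np.searchsorted(mdays, hi, side="right") - 1
                has_match = (pos >= 0) & (mdays[np.maximum(pos, 0)] > lo)
                eval_day = np.where(
                    has_match, mdays[np.maximum(pos, 0)], np.minimum(lo + 3, hi)
                )
            else:
                eval_day = np.minimum(lo + 3, hi)
            tw = h.count12(eval_day)
            if exclude_zero_twelve_month:
                zero = tw == 0
                report.n_excluded_zero_exposure += int(zero.sum())
                if event and zero[-1]:
                    report.n_excluded_events += 1
                retain = ~zero
                if not retain.any():
                    continue
            else:
                retain = np.ones(len(hi), dtype=bool)
            nseg = int(retain.sum())
            ev_flags = np.zeros(len(hi), dtype=bool)
            if event:
                ev_flags[-1] = True
            # team at the segment end follows the roster spans
            spans = span_rows[pid]
            if len(spans) == 1:
                team_seg = np.array([spans[0][2]] * len(hi), dtype=object)
            else:
                team_seg = np.array(
                    [next((t for en, ex, t in spans if en <= d <= ex), spans[-1][2]) for d in hi],
                    dtype=object,
                )
            iid = f"{pid}#{k}"
            out["interval_id"].extend([iid] * nseg)
            out["player_id"].extend([pid] * nseg)
            out["team_id"].extend(team_seg[retain].tolist())
            out["seg_start_date"].extend((epoch + pd.to_timedelta(lo[retain], unit="D")).tolist())
            out["seg_end_date"].extend((epoch + pd.to_timedelta(hi[retain], unit="D")).tolist())
            out["gap_start_hours"].extend(starts[retain].tolist())
            out["gap_stop_hours"].extend(stops[retain].tolist())
            out["event"].extend(ev_flags[retain].tolist())
            out["age"].extend(((eval_day[retain] - birth_day) / DAYS_PER_YEAR).tolist())
            out["height_cm"].extend([prof["height_cm"]] * nseg)
            out["mass_kg"].extend([prof["mass_kg"]] * nseg)
            out["position"].extend([prof["position"]] * nseg)
            out["prev_injury_count"].extend([int(n_prev)] * nseg)
            out["twelve_month_matches"].extend(tw[retain].astype(int).tolist())
            out["one_month_fge"].extend(h.fge1(eval_day)[retain].tolist())

    rows = pd.DataFrame(out)
    if len(rows):
        if breakpoints is None:
            breakpoints = quartile_breakpoints(rows["twelve_month_matches"])
        rows["twelve_month_quartile"] = assign_quartile(
            rows["twelve_month_matches"], breakpoints
        )
        report.n_intervals = rows["interval_id"].nunique()
        report.n_events = int(rows["event"].sum())
    else:
        rows["twelve_month_quartile"] = pd.Series(dtype=int)
    report.quartile_breakpoints = breakpoints
    return rows, report


def standardize_2sd(
    intervals: pd.DataFrame, covariate: str
) -> tuple[pd.Series, tuple[float, float]]:
    """Scale a continuous covariate to (x − mean) / (2·SD).

    A unit change on the transformed scale is a two-standard-deviation
    change on the original scale, so exp(beta) of the transformed column is
    the hazard ratio per 2-SD increase.  Returns the transformed column and
    the (mean, SD) scale report for back-transformation.
    """
    x = intervals[covariate].astype(float)
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if not np.isfinite(sd) or sd <= 0:
        raise ValueError(f"standardize_2sd: covariate {covariate!r} has zero SD")
    return (x - mean) / (2.0 * sd), (mean, sd)


def add_standardized(
    intervals: pd.DataFrame, covariates: list[str], suffix: str = "_2sd"
) -> tuple[pd.DataFrame, dict]:
    """Append 2-SD standardized copies of covariates; returns (df, scales)."""
    out = intervals.copy()
    scales = {}
    for cov in covariates:
        col, scale = standardize_2sd(intervals, cov)
        out[cov + suffix] = col
        scales[cov] = scale
    return out, scales


_DATE_COLS = ("start_date", "end_date", "seg_start_date", "seg_end_date")


def write_intervals(intervals: pd.DataFrame, path) -> None:
    out = intervals.copy()
    for c in _DATE_COLS:
        if c in out.columns:
            out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_intervals(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"player_id": str, "team_id": str})
    for c in _DATE_COLS:
        if c in df.columns:
            df[c] = pd.to_datetime(df[c], format="ISO8601")
    df["event"] = df["event"].astype(bool)
    return df
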