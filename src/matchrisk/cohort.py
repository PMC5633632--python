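"""Cohort table I/O and validation.

Four CSV tables describe a cohort (comma-separated, UTF-8, header row
mandatory, ISO-8601 dates):

``players.csv``
    player_id, team_id, birth_date, height_cm, mass_kg, position,
    entry_date, exit_date.  A player transferring between teams appears as
    multiple rows with disjoint [entry, exit) spans; exposure history
    follows the player across teams.
``matches.csv``
    player_id, team_id, match_date, minutes.
``training.csv``
    team_id, week_start (a Monday), hours — group training hours reported
    weekly per team.
``injuries.csv``
    player_id, injury_date, return_date, setting (match/training),
    diagnosis_code (optional OSICS pass-through).

All file exchange goes through :func:`read_cohort` / :func:`write_cohort`;
validation is total — malformed input raises a typed error, never a silent
coercion.  Missing height/mass/birth_date are hard errors: the downstream
models adjust for every covariate and perform no imputation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

POSITIONS = ("forward", "back")
SETTINGS = ("match", "training")

PLAYER_COLUMNS = [
    "player_id",
    "team_id",
    "birth_date",
    "height_cm",
    "mass_kg",
    "position",
    "entry_date",
    "exit_date",
]
MATCH_COLUMNS = ["player_id", "team_id", "match_date", "minutes"]
TRAINING_COLUMNS = ["team_id", "week_start", "hours"]
INJURY_COLUMNS = ["player_id", "injury_date", "return_date", "setting", "diagnosis_code"]

HEIGHT_RANGE = (120.0, 230.0)
MASS_RANGE = (50.0, 180.0)
MAX_MATCH_MINUTES = 100.0


class CohortError(Exception):
    """Base class for cohort I/O and validation failures."""


class SchemaError(CohortError):
    """A file does not conform to the documented column schema."""


class ReferentialError(CohortError):
    """A cross-table reference (player_id, team_id) cannot be resolved."""


class ValidationError(CohortError):
    """A table violates a domain invariant."""


@dataclass
class Cohort:
    """Validated bundle of the four cohort tables (pandas DataFrames)."""

    players: pd.DataFrame
    matches: pd.DataFrame
    training: pd.DataFrame
    injuries: pd.DataFrame

    def copy(self) -> "Cohort":
        return Cohort(
            self.players.copy(),
            self.matches.copy(),
            self.training.copy(),
            self.injuries.copy(),
        )


def _require_columns(df: pd.DataFrame, cols: list[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing column(s) {missing}")


def _parse_dates(df: pd.DataFrame, cols: list[str], table: str) -> None:
    for c in cols:
        try:
            df[c] = pd.to_datetime(df[c], format="ISO8601")
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{table}.{c}: unparseable ISO-8601 date ({exc})") from exc
        if df[c].isna().any():
            raise SchemaError(f"{table}.{c}: missing date value")


def _require_numeric(df: pd.DataFrame, col: str, table: str) -> None:
    vals = pd.to_numeric(df[col], errors="coerce")
    if vals.isna().any() and not df[col].isna().all():
        bad = df.index[vals.isna()].tolist()[:5]
        raise SchemaError(f"{table}.{col}: non-numeric values at rows {bad}")
    if df[col].isna().any():
        raise ValidationError(f"{table}.{col}: missing values are not allowed")
    df[col] = vals.astype(float)


def validate_cohort(cohort: Cohort) -> Cohort:
    """Check every type invariant and cross-reference; return the cohort.

    Raises
    ------
    SchemaError, ReferentialError, ValidationError
    """
    players = cohort.players
    matches = cohort.matches
    training = cohort.training
    injuries = cohort.injuries

    _require_columns(players, PLAYER_COLUMNS, "players")
    _require_columns(matches, MATCH_COLUMNS, "matches")
    _require_columns(training, TRAINING_COLUMNS, "training")
    _require_columns(injuries, INJURY_COLUMNS, "injuries")

    # --- players ---
    for col in ("player_id", "team_id"):
        if players[col].isna().any():
            raise ValidationError(f"players.{col}: missing identifier")
    _require_numeric(players, "height_cm", "players")
    _require_numeric(players, "mass_kg", "players")
    bad = players[
        ~players["height_cm"].between(*HEIGHT_RANGE, inclusive="neither")
    ]
    if len(bad):
        raise ValidationError(
            f"players.height_cm outside ({HEIGHT_RANGE[0]}, {HEIGHT_RANGE[1]}): "
            f"players {bad['player_id'].tolist()[:5]}"
        )
    bad = players[~players["mass_kg"].between(*MASS_RANGE, inclusive="neither")]
    if len(bad):
        raise ValidationError(
            f"players.mass_kg outside ({MASS_RANGE[0]}, {MASS_RANGE[1]}): "
            f"players {bad['player_id'].tolist()[:5]}"
        )
    unknown_pos = set(players["position"]) - set(POSITIONS)
    if unknown_pos:
        raise ValidationError(f"players.position: unknown level(s) {sorted(unknown_pos)}")
    if (players["exit_date"] < players["entry_date"]).any():
        bad = players[players["exit_date"] < players["entry_date"]]
        raise ValidationError(
            f"players: exit_date before entry_date for {bad['player_id'].tolist()[:5]}"
        )
    # disjoint roster spans per player
    spans = players.sort_values(["player_id", "entry_date"])
    prev_exit = spans.groupby("player_id")["exit_date"].shift()
    overlap = spans[prev_exit.notna() & (spans["entry_date"] < prev_exit)]
    if len(overlap):
        raise ValidationError(
            f"players: overlapping roster spans for {overlap['player_id'].unique().tolist()[:5]}"
        )

    roster_ids = set(players["player_id"])

    # --- matches ---
    _require_numeric(matches, "minutes", "matches")
    if (matches["minutes"] < 0).any():
        raise ValidationError("matches.minutes: negative values")
    if (matches["minutes"] > MAX_MATCH_MINUTES).any():
        raise ValidationError(f"matches.minutes: values above {MAX_MATCH_MINUTES}")
    orphans = set(matches["player_id"]) - roster_ids
    if orphans:
        raise ReferentialError(f"matches: unknown player_id(s) {sorted(orphans)[:5]}")
    # each involvement must fall inside one of the player's roster spans
    if len(matches):
        merged = matches.merge(
            players[["player_id", "entry_date", "exit_date"]], on="player_id", how="left"
        )
        inside = (merged["match_date"] >= merged["entry_date"]) & (
            merged["match_date"] <= merged["exit_date"]
        )
        covered = merged.assign(_inside=inside).groupby(level=0)["_inside"].any()
        # groupby(level=0) follows the original matches row index through the merge
        if not covered.all():
            bad_rows = covered.index[~covered].tolist()[:5]
            raise ValidationError(
                f"matches: match_date outside the player's [entry_date, exit_date] "
                f"at rows {bad_rows}"
            )

    # --- training ---
    _require_numeric(training, "hours", "training")
    if (training["hours"] < 0).any():
        raise ValidationError("training.hours: negative values")
    if len(training):
        if (training["week_start"].dt.dayofweek != 0).any():
            raise ValidationError("training.week_start: not a Monday")
        dup = training.duplicated(subset=["team_id", "week_start"])
        if dup.any():
            raise ValidationError(
                f"training: duplicate (team_id, week_start) at rows {training.index[dup].tolist()[:5]}"
            )

    # --- injuries ---
    orphans = set(injuries["player_id"]) - roster_ids
    if orphans:
        raise ReferentialError(f"injuries: unknown player_id(s) {sorted(orphans)[:5]}")
    unknown_set = set(injuries["setting"]) - set(SETTINGS)
    if unknown_set:
        raise ValidationError(f"injuries.setting: unknown level(s) {sorted(unknown_set)}")
    # time-loss definition: absence for more than 24 h => return strictly after injury
    if len(injuries):
        bad = injuries[injuries["return_date"] <= injuries["injury_date"]]
        if len(bad):
            raise ValidationError(
                "injuries: return_date must be strictly after injury_date "
                f"(time loss exceeds 24 h) at rows {bad.index.tolist()[:5]}"
            )
        inj = injuries.sort_values(["player_id", "injury_date"])
        prev_return = inj.groupby("player_id")["return_date"].shift()
        overlapping = inj[prev_return.notna() & (inj["injury_date"] < prev_return)]
        if len(overlapping):
            raise ValidationError(
                "injuries: overlapping injury spells for player(s) "
                f"{overlapping['player_id'].unique().tolist()[:5]} "
                f"at rows {overlapping.index.tolist()[:5]}"
            )

    return cohort


def read_cohort(
    players: str | Path,
    matches: str | Path,
    training: str | Path,
    injuries: str | Path,
) -> Cohort:
    """Read and validate the four cohort CSVs.

    Parameters are the four file locations. Returns a validated
    :class:`Cohort`; raises a typed :class:`CohortError` subclass on any
    schema, referential or invariant violation.
    """
    frames = {}
    for name, path, cols in (
        ("players", players, PLAYER_COLUMNS),
        ("matches", matches, MATCH_COLUMNS),
        ("training", training, TRAINING_COLUMNS),
        ("injuries", injuries, INJURY_COLUMNS),
    ):
        path = Path(path)
        if not path.exists():
            raise SchemaError(f"{name}: file not found: {path}")
        df = pd.read_csv(path, dtype={"player_id": str, "team_id": str})
        if "diagnosis_code" in df.columns:
            df["diagnosis_code"] = df["diagnosis_code"].astype("string")
        _require_columns(df, cols, name)
        frames[name] = df[cols].copy()

    _parse_dates(frames["players"], ["birth_date", "entry_date", "exit_date"], "players")
    _parse_dates(frames["matches"], ["match_date"], "matches")
    _parse_dates(frames["training"], ["week_start"], "training")
    _parse_dates(frames["injuries"], ["injury_date", "return_date"], "injuries")

    return validate_cohort(Cohort(**frames))


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the four tables under ``out_dir``; returns the file paths.

    ``read_cohort(**write_cohort(c))`` reproduces ``c`` exactly: dates in
    ISO-8601, numeric values at full (shortest round-tripping) precision.
    """
    validate_cohort(cohort)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df, datecols in (
        ("players", cohort.players, ["birth_date", "entry_date", "exit_date"]),
        ("matches", cohort.matches, ["match_date"]),
        ("training", cohort.training, ["week_start"]),
        ("injuries", cohort.injuries, ["injury_date", "return_date"]),
    ):
        out = df.copy()
        for c in datecols:
            out[c] = out[c].dt.strftime("%Y-%m-%d")
        path = out_dir / f"{name}.csv"
        out.to_csv(path, index=False)
        paths[name] = path
    return paths


def cohort_paths(directory: str | Path) -> dict[str, Path]:
    """Conventional file names of a cohort directory, for read_cohort(**...)."""
    d = Path(directory)
    return {
        "players": d / "players.csv",
        "matches": d / "matches.csv",
        "training": d / "training.csv",
        "injuries": d / "injuries.csv",
    }


def player_spans(players: pd.DataFrame) -> pd.DataFrame:
    """One row per player: overall entry (min) and exit (max) across spans."""
    g = players.groupby("player_id")
    out = pd.DataFrame(
        {
            "entry_date": g["entry_date"].min(),
            "exit_date": g["exit_date"].max(),
            "birth_date": g["birth_date"].first(),
            "height_cm": g["height_cm"].first(),
            "mass_kg": g["mass_kg"].first(),
            "position": g["position"].first(),
            # team of the latest span, used when a single label is needed
            "team_id": players.sort_values("entry_date").groupby("player_id")["team_id"].last(),
        }
    )
    return out
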