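"""Validated CSV I/O for the cohort tables.

Schemas (all plain CSV with a header row):

sessions.csv  — animal_id, genotype, sex, week, session_index,
                time_pulling_s, time_hindlimbs_s, length_pulled_cm
weights.csv   — animal_id, genotype, sex, week, weight_g
histology.csv — animal_id, genotype, week, region, slice_id, mn_count,
                field_area_px
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .config import GENOTYPES, REGIONS, SEXES
from .simulate import (CohortDataset, HISTOLOGY_COLUMNS, SESSION_COLUMNS,
                       WEIGHT_COLUMNS)


class TableValidationError(ValueError):
    """One or more rows or columns violate the documented schema."""

    def __init__(self, table: str, problems: list):
        self.table = table
        self.problems = list(problems)
        detail = "; ".join(self.problems[:10])
        more = "" if len(self.problems) <= 10 else f" (+{len(self.problems) - 10} more)"
        super().__init__(f"{table}: {detail}{more}")


def _require_columns(df: pd.DataFrame, required, table: str, problems: list):
    missing = [c for c in required if c not in df.columns]
    if missing:
        problems.append(f"missing column(s) {missing}")
    return not missing


def _bad_rows(mask, message, problems, limit=5):
    idx = list(mask[mask].index[:limit])
    if idx:
        problems.append(f"{message} at row(s) {idx}")


def load_sessions(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    problems: list = []
    if _require_columns(df, SESSION_COLUMNS, "sessions", problems):
        _bad_rows(~df["genotype"].isin(GENOTYPES), "bad genotype", problems)
        _bad_rows(~df["sex"].isin(SEXES), "bad sex", problems)
        _bad_rows(df["week"] < 0, "negative week", problems)
        for col in ("time_pulling_s", "time_hindlimbs_s", "length_pulled_cm"):
            _bad_rows(df[col] < 0, f"negative {col}", problems)
        _bad_rows(df["time_pulling_s"] > 60, "time_pulling_s > 60", problems)
        _bad_rows(df["time_hindlimbs_s"] > df["time_pulling_s"] + 1e-9,
                  "time_hindlimbs_s exceeds time_pulling_s", problems)
        dup = df.duplicated(subset=["animal_id", "week", "session_index"], keep=False)
        if dup.any():
            keys = df.loc[dup, ["animal_id", "week", "session_index"]].drop_duplicates()
            problems.append(
                "duplicate (animal_id, week, session_index) keys: "
                + ", ".join(f"({r.animal_id}, {r.week}, {r.session_index})"
                            for r in keys.head(5).itertuples()))
    if problems:
        raise TableValidationError("sessions", problems)
    return df[SESSION_COLUMNS]


def load_weights(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    problems: list = []
    if _require_columns(df, WEIGHT_COLUMNS, "weights", problems):
        _bad_rows(~df["genotype"].isin(GENOTYPES), "bad genotype", problems)
        _bad_rows(~df["sex"].isin(SEXES), "bad sex", problems)
        _bad_rows(df["weight_g"] < 0, "negative weight", problems)
        dup = df.duplicated(subset=["animal_id", "week"], keep=False)
        if dup.any():
            keys = df.loc[dup, ["animal_id", "week"]].drop_duplicates()
            problems.append("duplicate (animal_id, week) keys: "
                            + ", ".join(f"({r.animal_id}, {r.week})"
                                        for r in keys.head(5).itertuples()))
    if problems:
        raise TableValidationError("weights", problems)
    return df[WEIGHT_COLUMNS]


def load_histology(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    problems: list = []
    if _require_columns(df, HISTOLOGY_COLUMNS, "histology", problems):
        _bad_rows(~df["genotype"].isin(GENOTYPES), "bad genotype", problems)
        _bad_rows(~df["region"].isin(REGIONS), "bad region", problems)
        _bad_rows(df["mn_count"] < 0, "negative mn_count", problems)
        _bad_rows(df["field_area_px"] <= 0, "nonpositive field_area_px", problems)
        dup = df.duplicated(subset=["slice_id", "region"], keep=False)
        if dup.any():
            problems.append("duplicate slice_id keys: "
                            + ", ".join(map(str, df.loc[dup, "slice_id"].unique()[:5])))
    if problems:
        raise TableValidationError("histology", problems)
    return df[HISTOLOGY_COLUMNS]


def load_tables(directory, config=None) -> CohortDataset:
    """Load and validate sessions/weights/histology CSVs from a directory."""
    d = Path(directory)
    return CohortDataset(
        sessions=load_sessions(d / "sessions.csv"),
        weights=load_weights(d / "weights.csv"),
        histology=load_histology(d / "histology.csv"),
        config=config,
    )
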