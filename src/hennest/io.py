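"""Reading and writing the package's four file kinds.

All files are plain CSV (comma separator, header row, UTF-8, "." decimal).
Times are integer minutes after lights-on; ``day_index`` counts 0-based days
from the start of the recording window, which sidesteps calendar arithmetic
entirely.  Unknown parents in pedigree files are encoded ``0``.

File kinds
----------
events     one row per nest visit:
           hen_id, day_index, nest_pos, nest_row (top|bottom), entry_min,
           exit_min, egg (0|1), ovi_min (empty if no egg), ovi_accurate (0|1)
pedigree   id, sire, dam  (0 = unknown; parents precede offspring)
traits     one row per hen, one column per derived trait; empty cell = the
           phenotype is missing (filtered out)
estimates  long-format genetic parameters: trait_i, trait_j, parameter,
           value, se
"""

from __future__ import annotations

import graphlib
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("hennest")

EVENT_COLUMNS = [
    "hen_id", "day_index", "nest_pos", "nest_row", "entry_min",
    "exit_min", "egg", "ovi_min", "ovi_accurate",
]

#: column order of the per-hen trait table (fixed and documented here)
TRAIT_COLUMNS = [
    "hen_id", "LRN", "CN", "MOT", "MOT_OVI", "MTE", "MDN", "PNL",
    "MLD", "MDB", "MDA", "NAL",
]

#: column order of the per-(hen, period) duration-trait table
PERIOD_TRAIT_COLUMNS = ["hen_id", "period", "MLD", "MDB", "MDA"]

ESTIMATE_COLUMNS = ["trait_i", "trait_j", "parameter", "value", "se"]


class SchemaError(ValueError):
    """A file does not conform to its documented schema."""


def log_filter(rule: str, n_before: int, n_after: int) -> None:
    """Log a record-count transition for one filtering rule (key=value)."""
    logger.info("filter rule=%s n_before=%d n_after=%d", rule, n_before, n_after)


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

def validate_events(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an in-memory event table; return it sorted (hen, day, entry).

    Raises :class:`SchemaError` naming the first offending line and field.
    Line numbers refer to the CSV file (header = line 1).
    """
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"event file missing columns: {missing}")
    df = df[EVENT_COLUMNS].copy()
    if len(df) == 0:
        return df

    def _bad(mask: pd.Series, field: str, why: str) -> None:
        if mask.any():
            line = int(df.index[mask][0]) + 2
            raise SchemaError(f"line {line}, field '{field}': {why}")

    _bad(~df["nest_row"].isin(["top", "bottom"]), "nest_row",
         "must be 'top' or 'bottom'")
    for field in ("day_index", "nest_pos", "entry_min", "exit_min"):
        _bad(df[field].isna(), field, "missing value")
    _bad(df["exit_min"] <= df["entry_min"], "exit_min",
         "exit must be after entry")
    _bad(~df["egg"].isin([0, 1]), "egg", "must be 0 or 1")
    _bad((df["egg"] == 0) & df["ovi_min"].notna(), "ovi_min",
         "oviposition time present on a visit without an egg")
    acc = (df["egg"] == 1) & (df["ovi_accurate"] == 1) & df["ovi_min"].notna()
    _bad(acc & ((df["ovi_min"] < df["entry_min"]) | (df["ovi_min"] > df["exit_min"])),
         "ovi_min", "accurate oviposition time outside the visit interval")
    out = df.sort_values(["hen_id", "day_index", "entry_min"], kind="mergesort")
    return out.reset_index(drop=True)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"hen_id": np.int64}, keep_default_na=True)
    df = validate_events(df)
    logger.info("read_events path=%s n=%d", path, len(df))
    return df


def write_events(df: pd.DataFrame, path) -> None:
    out = df[EVENT_COLUMNS].copy()
    # ovi_min written as integer-or-empty, not float
    out["ovi_min"] = out["ovi_min"].astype("Int64")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def validate_pedigree(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and topologically order a pedigree (parents first).

    A cycle raises :class:`SchemaError` listing the individuals involved.
    """
    for c in ("id", "sire", "dam"):
        if c not in df.columns:
            raise SchemaError(f"pedigree file missing column '{c}'")
    df = df[["id", "sire", "dam"]].astype(np.int64)
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise SchemaError(f"duplicate individual id {dup}")
    if (df["id"] == 0).any():
        raise SchemaError("0 is reserved for unknown parents, not an id")
    ids = set(df["id"])
    for c in ("sire", "dam"):
        bad = ~df[c].isin(ids) & (df[c] != 0)
        if bad.any():
            raise SchemaError(
                f"unknown {c} id {int(df.loc[bad, c].iloc[0])} "
                f"(parents must appear in the file or be 0)")
    ts: graphlib.TopologicalSorter = graphlib.TopologicalSorter()
    for _, row in df.iterrows():
        preds = [p for p in (row["sire"], row["dam"]) if p != 0]
        ts.add(row["id"], *preds)
    try:
        order = list(ts.static_order())
    except graphlib.CycleError as err:
        raise SchemaError(f"pedigree contains a cycle: {err.args[1]}") from err
    rank = {ind: i for i, ind in enumerate(order)}
    out = df.sort_values("id", key=lambda s: s.map(rank), kind="mergesort")
    return out.reset_index(drop=True)


def read_pedigree(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df = validate_pedigree(df)
    logger.info("read_pedigree path=%s n=%d", path, len(df))
    return df


def write_pedigree(df: pd.DataFrame, path) -> None:
    df[["id", "sire", "dam"]].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def write_traits(df: pd.DataFrame, path) -> None:
    """Write a trait table with explicit empty cells for missing phenotypes."""
    cols = TRAIT_COLUMNS if "period" not in df.columns else PERIOD_TRAIT_COLUMNS
    df[cols].to_csv(path, index=False, na_rep="")


def read_traits(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    cols = TRAIT_COLUMNS if "period" not in df.columns else PERIOD_TRAIT_COLUMNS
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"trait file missing columns: {missing}")
    return df[cols]


# ---------------------------------------------------------------------------
# estimates
# ---------------------------------------------------------------------------

def write_estimates(df: pd.DataFrame, path) -> None:
    df[ESTIMATE_COLUMNS].to_csv(path, index=False, na_rep="")


def read_estimates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ESTIMATE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"estimate file missing columns: {missing}")
    return df[ESTIMATE_COLUMNS]
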