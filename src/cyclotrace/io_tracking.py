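"""Reading tracker exports and writing/reading the curated per-cell database.

The per-frame export format of tracking plugins varies, so column names are
mapped through a configurable ``column_map`` (defaults to the canonical
names). Validation is split into *fatal* integrity errors (missing columns,
ancestry cycles, more than two children per parent) and *row-level*
violations, which drop the offending rows but report every one of them, so
no row is ever silently discarded.
"""

from __future__ import annotations

import os
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .datamodel import (
    RECORD_COLUMNS,
    TRACKING_COLUMNS,
    Condition,
    DatasetMetadata,
    TrackingTable,
    Violation,
)

__all__ = [
    "SchemaError",
    "LineageError",
    "IntegrityError",
    "DEFAULT_COLUMN_MAP",
    "read_tracking_table",
    "validate_tracking_frame",
    "write_database",
    "read_database",
]


class SchemaError(ValueError):
    """A required column is missing or unmappable."""


class LineageError(ValueError):
    """Parent/child links are inconsistent (cycles, time travel)."""


class IntegrityError(ValueError):
    """Structural violation, e.g. a parent with more than two children."""


#: identity mapping: export column name -> canonical name
DEFAULT_COLUMN_MAP: Mapping[str, str] = {c: c for c in TRACKING_COLUMNS}

_NULL_PARENT = {"", "none", "nan", "null", "-1", "na"}


def read_tracking_table(
    path: str | os.PathLike,
    metadata: DatasetMetadata,
    column_map: Optional[Mapping[str, str]] = None,
    sep: str = ",",
    time_tolerance_h: float = 1e-6,
) -> TrackingTable:
    """Read a delimited per-frame export into a validated :class:`TrackingTable`.

    Parameters
    ----------
    path:
        CSV/TSV file with one row per (cell, frame).
    metadata:
        Frame interval / window used to cross-check the time column.
    column_map:
        Mapping from the file's column names to the canonical schema; any
        canonical column not covered by the map must be present verbatim.
    """
    raw = pd.read_csv(path, sep=sep, dtype={})
    cmap = dict(column_map or DEFAULT_COLUMN_MAP)
    rename = {src: dst for src, dst in cmap.items() if src in raw.columns}
    df = raw.rename(columns=rename)
    missing = [c for c in TRACKING_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    df = df[TRACKING_COLUMNS].copy()
    return validate_tracking_frame(df, metadata, time_tolerance_h=time_tolerance_h)


def validate_tracking_frame(
    df: pd.DataFrame,
    metadata: DatasetMetadata,
    time_tolerance_h: float = 1e-6,
) -> TrackingTable:
    """Validate a canonical-column frame; fatal errors raise, row errors drop."""
    df = df.reset_index(drop=True).copy()
    df["cell_id"] = df["cell_id"].astype(str)
    df["colony_id"] = df["colony_id"].astype(str)
    df["condition"] = [Condition.parse(c).value for c in df["condition"]]
    df["frame"] = df["frame"].astype(int)
    parent = df["parent_id"].astype(str).str.strip()
    df["parent_id"] = parent.where(~parent.str.lower().isin(_NULL_PARENT), other="")

    violations: list[Violation] = []
    bad = np.zeros(len(df), dtype=bool)

    neg = (df["cherry"] < 0) | (df["venus"] < 0) | (df["nuclear_area"] < 0)
    for i in np.flatnonzero(neg.to_numpy()):
        violations.append(Violation(int(i), "negative_value", "negative fluorescence or area"))
    bad |= neg.to_numpy()

    dt = metadata.frame_interval_h
    drift = np.abs(df["time_h"].to_numpy() - df["frame"].to_numpy() * dt)
    toff = drift > max(time_tolerance_h, 1e-9)
    for i in np.flatnonzero(toff & ~bad):
        violations.append(
            Violation(int(i), "time_mismatch", f"time_h != frame * {dt} (off by {drift[i]:.4g} h)")
        )
    bad |= toff

    # frames strictly increasing within each cell (checked on surviving rows)
    keep = df.loc[~bad]
    order_bad_idx: list[int] = []
    for _, g in keep.groupby("cell_id", sort=False):
        f = g["frame"].to_numpy()
        dup = np.flatnonzero(np.diff(f) <= 0) + 1
        order_bad_idx.extend(int(g.index[j]) for j in dup)
    for i in order_bad_idx:
        violations.append(Violation(i, "frame_order", "frames not strictly increasing for cell"))
        bad[i] = True

    clean = df.loc[~bad].reset_index(drop=True)

    _check_lineage(clean)
    gap_cells = _single_child_parents(clean)

    return TrackingTable(
        df=clean,
        metadata=metadata,
        violations=violations,
        track_gap_cells=frozenset(gap_cells),
    )


def _check_lineage(df: pd.DataFrame) -> None:
    first = df.groupby("cell_id")["frame"].min()
    last = df.groupby("cell_id")["frame"].max()
    colony = df.groupby("cell_id")["colony_id"].first()
    parent_of: dict[str, str] = {}
    for cid, g in df.groupby("cell_id"):
        parents = set(p for p in g["parent_id"] if p)
        if len(parents) > 1:
            raise LineageError(f"cell {cid} lists multiple parents: {sorted(parents)}")
        if parents:
            parent_of[cid] = parents.pop()

    children_count: dict[str, int] = {}
    for cid, pid in parent_of.items():
        if pid not in first.index:
            raise LineageError(f"cell {cid} references unknown parent {pid}")
        if colony[pid] != colony[cid]:
            raise LineageError(f"cell {cid} and parent {pid} are in different colonies")
        if last[pid] >= first[cid]:
            raise LineageError(
                f"parent {pid} still tracked at frame {last[pid]} but child {cid} "
                f"starts at frame {first[cid]}"
            )
        children_count[pid] = children_count.get(pid, 0) + 1

    for pid, n in children_count.items():
        if n > 2:
            raise IntegrityError(f"parent {pid} has {n} children (max 2)")

    # cycle check (time ordering above already precludes cycles, but links
    # could be pathological if frames were equal; keep an explicit walk)
    for start in parent_of:
        seen = {start}
        cur = start
        while cur in parent_of:
            cur = parent_of[cur]
            if cur in seen:
                raise LineageError(f"ancestry cycle involving cell {cur}")
            seen.add(cur)


def _single_child_parents(df: pd.DataFrame) -> set[str]:
    links = (
        df.loc[df["parent_id"] != ""]
        .groupby("cell_id")["parent_id"]
        .first()
        .reset_index()
    )
    counts = links.groupby("parent_id").size()
    return set(counts.index[counts == 1])


def write_database(records: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write the curated per-cell database as CSV with a stable column order."""
    out = records.copy()
    for col in RECORD_COLUMNS:
        if col not in out.columns:
            raise SchemaError(f"record table missing column {col!r}")
    out = out[RECORD_COLUMNS]
    out.to_csv(path, index=False, float_format="%.10g")


def read_database(path: str | os.PathLike) -> pd.DataFrame:
    """Read a per-cell database written by :func:`write_database`."""
    df = pd.read_csv(
        path,
        dtype={"cell_id": str, "colony_id": str, "parent_id": str, "fate": str},
    )
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"database missing columns: {missing}")
    df["parent_id"] = df["parent_id"].fillna("")
    df["complete"] = df["complete"].astype(bool)
    df["track_gap"] = df["track_gap"].astype(bool)
    df["generation"] = df["generation"].astype(int)
    return df[RECORD_COLUMNS]
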