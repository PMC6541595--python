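"""Trajectory and colony morphology metrics.

Per-cell metrics (complete cells only): total trajectory length, mean speed
(path / cycle length), convex-hull area of the trajectory and exploration
(hull area / cycle length) — both normalizations remove the bias a longer
cycle would otherwise introduce. Per colony-frame: convex-hull area of
member centroids and cell density. A cell is peripheral when, at any frame
of its life, its centroid lies within one nuclear radius of its colony's
hull boundary.
"""

from __future__ import annotations

import math
import warnings
from typing import Optional

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint

from .datamodel import TrackingTable

__all__ = [
    "path_length",
    "convex_hull_area",
    "motility_summary",
    "colony_metrics",
    "classify_peripheral",
    "nuclear_area_summary",
]

MAX_GAP_FRAMES = 4  # longer tracking gaps split the path instead of bridging it


def path_length(frames: np.ndarray, x: np.ndarray, y: np.ndarray,
                max_gap: int = MAX_GAP_FRAMES) -> float:
    """Total trajectory length: summed consecutive segment lengths.

    Short gaps (<= ``max_gap`` frames) are bridged by a straight segment
    (equivalent to linear interpolation); longer gaps split the path.
    """
    frames = np.asarray(frames)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2:
        warnings.warn("trajectory with < 2 points: path length 0")
        return 0.0
    order = np.argsort(frames)
    f, xs, ys = frames[order], x[order], y[order]
    seg = np.hypot(np.diff(xs), np.diff(ys))
    keep = np.diff(f) <= max_gap
    return float(seg[keep].sum())


def convex_hull_area(points: np.ndarray) -> float:
    """Area of the 2D convex hull; 0 for fewer than 3 non-collinear points."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) < 3:
        return 0.0
    return float(MultiPoint(points).convex_hull.area)


def motility_summary(
    records: pd.DataFrame,
    table: TrackingTable,
    peripheral: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Per-cell speed and exploration metrics for complete cells.

    Requires >= 3 trajectory points per cell; ``peripheral`` (cell_id ->
    bool, from :func:`classify_peripheral`) is joined when provided.
    """
    df = table.df
    complete = records.loc[records["complete"]].set_index("cell_id")
    rows = []
    for cid, g in df.groupby("cell_id", sort=False):
        if cid not in complete.index:
            continue
        if len(g) < 3:
            warnings.warn(f"cell {cid}: fewer than 3 trajectory points, skipped")
            continue
        cc = float(complete.at[cid, "cc_l_h"])
        pl = path_length(g["frame"].to_numpy(), g["x"].to_numpy(), g["y"].to_numpy())
        hull = convex_hull_area(g[["x", "y"]].to_numpy())
        rows.append({
            "cell_id": cid,
            "colony_id": complete.at[cid, "colony_id"],
            "condition": complete.at[cid, "condition"],
            "generation": int(complete.at[cid, "generation"]),
            "cc_l_h": cc,
            "path_length": pl,
            "mean_speed": pl / cc,
            "hull_area": hull,
            "exploration": hull / cc,
            "peripheral": bool(peripheral.get(cid, False)) if peripheral is not None else pd.NA,
        })
    return pd.DataFrame(rows)


def colony_metrics(table: TrackingTable) -> pd.DataFrame:
    """Per colony-frame hull area of member centroids and cell density.

    Density is undefined (NaN) for degenerate hulls (< 3 cells or
    collinear positions).
    """
    rows = []
    for (colony, frame), g in table.df.groupby(["colony_id", "frame"], sort=True):
        n = len(g)
        area = convex_hull_area(g[["x", "y"]].to_numpy())
        rows.append({
            "colony_id": colony,
            "condition": g["condition"].iloc[0],
            "frame": int(frame),
            "time_h": float(g["time_h"].iloc[0]),
            "n_cells": n,
            "colony_area": area,
            "density": n / area if area > 0 else float("nan"),
        })
    return pd.DataFrame(rows)


def classify_peripheral(
    table: TrackingTable, eps: Optional[float] = None
) -> pd.Series:
    """Peripheral flag per cell: touches the colony hull at some frame.

    A cell is peripheral when in >= 1 frame of its life its centroid lies
    within ``eps`` of its colony's convex-hull boundary. ``eps`` defaults
    to one nuclear radius estimated from the median nuclear area. Frames
    with a degenerate hull (<= 2 cells, or all collinear) make every
    member peripheral.
    """
    df = table.df
    if eps is None:
        med_area = float(df["nuclear_area"].median())
        eps = math.sqrt(max(med_area, 0.0) / math.pi)
    flags: dict[str, bool] = {cid: False for cid in df["cell_id"].unique()}
    for (_, _), g in df.groupby(["colony_id", "frame"], sort=False):
        pts = g[["x", "y"]].to_numpy()
        hull = MultiPoint(pts).convex_hull
        if hull.area == 0:  # point, segment or collinear set: all on the hull
            for cid in g["cell_id"]:
                flags[cid] = True
            continue
        boundary = hull.exterior
        dists = shapely.distance(shapely.points(pts), boundary)
        for cid, d in zip(g["cell_id"], dists):
            if d <= eps:
                flags[cid] = True
    return pd.Series(flags, name="peripheral")


def nuclear_area_summary(
    table: TrackingTable, records: pd.DataFrame
) -> pd.DataFrame:
    """Per-cell mean nuclear area with condition/generation labels."""
    if "nuclear_area" not in table.df.columns:
        warnings.warn("nuclear_area column absent; skipping area summary")
        return pd.DataFrame(columns=["cell_id", "condition", "generation", "mean_area"])
    mean_area = table.df.groupby("cell_id")["nuclear_area"].mean()
    rec = records.set_index("cell_id")
    rows = []
    for cid, area in mean_area.items():
        if cid not in rec.index:
            continue
        rows.append({
            "cell_id": cid,
            "condition": rec.at[cid, "condition"],
            "generation": int(rec.at[cid, "generation"]),
            "mean_area": float(area),
        })
    return pd.DataFrame(rows)
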