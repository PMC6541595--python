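"""Per-cell cycle metrics from per-frame traces.

Converts a validated tracking table into one record per cell: generation,
fate, cycle length (birth to division), G1 length (birth to the local
maximum of the G1-reporter trace) and the S-G2-M length by subtraction.
Birth and division instants are placed mid-way between a parent's last
frame and its daughters' first frame, so sisters share their birth time
exactly and cycle lengths land on the frame grid.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .datamodel import (
    RECORD_COLUMNS,
    DatasetMetadata,
    Fate,
    TrackingTable,
    duration_on_grid,
)

__all__ = [
    "TraceTooShortError",
    "assign_generations",
    "detect_g1_boundary",
    "extract_records",
    "filter_complete",
]


class TraceTooShortError(ValueError):
    """Trace has too few observations for a boundary call (distinct from a null call)."""


def assign_generations(parent: Mapping[str, str] | object) -> dict[str, int]:
    """Generation per cell: founders (no parent) are 1, children parent+1.

    Accepts a ``cell_id -> parent_id`` mapping (empty string / missing =
    founder) or any object with a ``.parent`` mapping attribute.
    """
    pmap = getattr(parent, "parent", parent)
    gen: dict[str, int] = {}

    def resolve(cid: str, trail: set[str]) -> int:
        if cid in gen:
            return gen[cid]
        pid = pmap.get(cid, "")
        if not pid:
            gen[cid] = 1
            return 1
        if pid in trail:
            raise ValueError(f"ancestry cycle involving {cid}")
        g = resolve(pid, trail | {cid}) + 1
        gen[cid] = g
        return g

    for cid in pmap:
        resolve(cid, set())
    return gen


def detect_g1_boundary(
    times_h: np.ndarray,
    intensity: np.ndarray,
    birth_time_h: float,
    end_time_h: float,
    smooth_window: int = 3,
    prominence_frac: float = 0.10,
) -> Optional[float]:
    """Time of the G1/S boundary: the peak of the smoothed G1-reporter trace.

    Returns the time of the global maximum of the moving-average-smoothed
    trace restricted to ``(birth, end)``, provided it is a genuine local
    maximum exceeding a prominence floor; ``None`` when the trace is
    monotone or flat (boundary not callable within the observed life).

    Raises
    ------
    TraceTooShortError
        Fewer than 5 observations in the window.
    """
    times_h = np.asarray(times_h, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    mask = (times_h > birth_time_h) & (times_h < end_time_h)
    t, y = times_h[mask], intensity[mask]
    if len(t) < 5:
        raise TraceTooShortError(f"only {len(t)} observations inside (birth, end)")
    s = uniform_filter1d(y, size=smooth_window, mode="nearest")
    j = int(np.argmax(s))
    if j == 0 or j == len(s) - 1:
        return None
    rng = float(s.max() - s.min())
    if rng <= 0:
        return None
    if not (s[j] > s[j - 1] and s[j] >= s[j + 1]):
        return None
    if (s[j] - s.min()) < prominence_frac * rng:
        return None
    return float(t[j])


def extract_records(
    table: TrackingTable,
    metadata: Optional[DatasetMetadata] = None,
    overrides: Optional[pd.DataFrame] = None,
    smooth_window: int = 3,
    prominence_frac: float = 0.10,
) -> pd.DataFrame:
    """One :data:`RECORD_COLUMNS` row per tracked cell.

    ``overrides`` mimics manual curation: an optional table with
    ``cell_id`` plus any of ``fate`` (e.g. annotating apoptosis) and
    ``boundary_time_h`` (correcting a failed peak call).
    """
    meta = metadata or table.metadata
    dt = meta.frame_interval_h
    final_frame = meta.n_frames - 1
    df = table.df

    grouped = df.groupby("cell_id", sort=False)
    first = grouped["frame"].min()
    last = grouped["frame"].max()
    head = grouped[["colony_id", "condition", "parent_id"]].first()

    pmap = {cid: head.at[cid, "parent_id"] for cid in head.index}
    generations = assign_generations(pmap)

    ov_fate: dict[str, str] = {}
    ov_boundary: dict[str, float] = {}
    if overrides is not None and len(overrides):
        for _, row in overrides.iterrows():
            cid = str(row["cell_id"])
            if "fate" in overrides.columns and isinstance(row.get("fate"), str) and row["fate"]:
                ov_fate[cid] = row["fate"]
            if "boundary_time_h" in overrides.columns and np.isfinite(
                row.get("boundary_time_h", float("nan"))
            ):
                ov_boundary[cid] = float(row["boundary_time_h"])

    n_children = pd.Series(pmap).replace("", np.nan).dropna().value_counts()

    rows = []
    for cid in head.index:
        pid = pmap[cid]
        kids = int(n_children.get(cid, 0))
        birth = (last[pid] + 0.5) * dt if pid else float("nan")
        divided = kids == 2
        if divided:
            fate = Fate.DIVIDED
            end = (last[cid] + 0.5) * dt
        else:
            end = last[cid] * dt
            if ov_fate.get(cid) == Fate.APOPTOSIS.value:
                fate = Fate.APOPTOSIS
            elif last[cid] >= final_frame:
                fate = Fate.CENSORED_END
            else:
                fate = Fate.TRACK_LOST
        complete = divided and bool(pid)
        cc = duration_on_grid(birth, end, dt) if complete else float("nan")

        g1 = sg2m = float("nan")
        if complete:
            boundary = ov_boundary.get(cid)
            if boundary is None:
                g = df.loc[grouped.groups[cid]]
                try:
                    boundary = detect_g1_boundary(
                        g["time_h"].to_numpy(), g["cherry"].to_numpy(),
                        birth, end,
                        smooth_window=smooth_window,
                        prominence_frac=prominence_frac,
                    )
                except TraceTooShortError:
                    boundary = None
            if boundary is not None:
                cand = duration_on_grid(birth, boundary, dt)
                if 0 < cand < cc:
                    g1 = cand
                    sg2m = cc - g1

        rows.append({
            "cell_id": cid,
            "colony_id": head.at[cid, "colony_id"],
            "condition": head.at[cid, "condition"],
            "parent_id": pid,
            "generation": generations[cid],
            "birth_time_h": birth,
            "end_time_h": end,
            "fate": fate.value,
            "cc_l_h": cc,
            "g1_l_h": g1,
            "sg2m_l_h": sg2m,
            "complete": complete,
            "track_gap": cid in table.track_gap_cells or pid in table.track_gap_cells,
        })
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def filter_complete(records: pd.DataFrame) -> pd.DataFrame:
    """Keep only cells with both birth and division observed.

    Generation-1 cells are necessarily excluded (birth not observed), as
    are cells reaching the end of the video and lost tracks.
    """
    return records.loc[records["complete"]].reset_index(drop=True)
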