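"""Core data model shared by all pipeline stages.

Two tabular schemas flow through the pipeline:

* the *tracking table* — one row per (cell, frame), as exported by
  nuclear-tracking software and by the simulator;
* the *record table* — one row per cell, holding derived cycle metrics
  (cycle length, phase lengths, fate, censoring information).

Both are plain :class:`pandas.DataFrame` objects with canonical column
names; thin wrapper classes carry metadata and validation state.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "Fate",
    "Relation",
    "DatasetMetadata",
    "TrackingTable",
    "Violation",
    "TRACKING_COLUMNS",
    "RECORD_COLUMNS",
    "duration_on_grid",
]


class Condition(str, enum.Enum):
    """Culture condition of a colony."""

    GROUND_STATE = "2i+LIF"
    DIFF = "Diff"

    @classmethod
    def parse(cls, label: str) -> "Condition":
        key = str(label).strip().lower()
        aliases = {
            "2i+lif": cls.GROUND_STATE,
            "2i + lif": cls.GROUND_STATE,
            "ground_state": cls.GROUND_STATE,
            "ground": cls.GROUND_STATE,
            "naive": cls.GROUND_STATE,
            "diff": cls.DIFF,
            "differentiation": cls.DIFF,
            "formative": cls.DIFF,
        }
        if key in aliases:
            return aliases[key]
        raise ValueError(f"unknown condition label: {label!r}")


class Fate(str, enum.Enum):
    """How a tracked cell's record ends."""

    DIVIDED = "DIVIDED"
    APOPTOSIS = "APOPTOSIS"
    CENSORED_END = "CENSORED_END"  # still alive at the end of the video
    TRACK_LOST = "TRACK_LOST"      # disappears before the video ends


class Relation(str, enum.Enum):
    SISTER = "SISTER"
    MOTHER_DAUGHTER = "MOTHER_DAUGHTER"
    COUSIN = "COUSIN"


#: canonical per-frame tracking columns, in storage order
TRACKING_COLUMNS = [
    "cell_id",
    "colony_id",
    "condition",
    "frame",
    "time_h",
    "x",
    "y",
    "nuclear_area",
    "cherry",
    "venus",
    "parent_id",
]

#: canonical per-cell record columns, in storage order
RECORD_COLUMNS = [
    "cell_id",
    "colony_id",
    "condition",
    "parent_id",
    "generation",
    "birth_time_h",
    "end_time_h",
    "fate",
    "cc_l_h",
    "g1_l_h",
    "sg2m_l_h",
    "complete",
    "track_gap",
]


@dataclass(frozen=True)
class DatasetMetadata:
    """Acquisition metadata needed to interpret a tracking table."""

    frame_interval_h: float = 0.25
    window_h: float = 45.0
    spatial_units: str = "px"

    def __post_init__(self) -> None:
        if self.frame_interval_h <= 0:
            raise ValueError("frame_interval_h must be > 0")
        if self.window_h <= 0:
            raise ValueError("window_h must be > 0")

    @property
    def n_frames(self) -> int:
        """Number of frames in the window, inclusive of frame 0."""
        return int(round(self.window_h / self.frame_interval_h)) + 1


@dataclass(frozen=True)
class Violation:
    """A non-fatal schema violation attached to specific input rows."""

    row: int
    code: str
    message: str


@dataclass
class TrackingTable:
    """Validated per-frame observations plus acquisition metadata.

    ``df`` holds the canonical columns of :data:`TRACKING_COLUMNS`;
    ``violations`` lists dropped/flagged rows so that
    ``len(raw rows) == len(df) + len(violations)`` always holds.
    """

    df: pd.DataFrame
    metadata: DatasetMetadata
    violations: list[Violation] = field(default_factory=list)
    track_gap_cells: frozenset[str] = frozenset()
    truth: Optional[pd.DataFrame] = None  # set by the simulator only

    def cells(self) -> list[str]:
        return list(self.df["cell_id"].unique())

    def __len__(self) -> int:  # number of observations
        return len(self.df)


def duration_on_grid(start_h: float, end_h: float, dt_h: float) -> float:
    """Snap a duration to the frame grid (half-up rounding).

    Division instants sit mid-way between frames while fluorescence peaks
    sit on frames, so raw differences can land on half-grid values; all
    reported durations are multiples of the frame interval.
    """
    if np.isnan(start_h) or np.isnan(end_h):
        return float("nan")
    return float(np.floor((end_h - start_h) / dt_h + 0.5 + 1e-9) * dt_h)
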