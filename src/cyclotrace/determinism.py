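"""Correlation-dimension analysis of lineage-embedded cycle variables.

A phase variable is read along ancestor chains — (mother, daughter) for
embedding dimension 2, (grandmother, mother, daughter) for 3 — giving a
point cloud whose correlation integral C(r) scales like r^nu over an
intermediate range. For independent-and-identically-distributed values the
cloud fills the embedding space (nu ~ m); inherited deterministic structure
confines it to a lower-dimensional set. The verdict compares the fitted
exponent against surrogates in which the variable is shuffled across cells
within (colony x generation) strata, destroying lineage linkage while
preserving the marginals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .lineage import LineageForest
from .survival import VARIABLES

__all__ = [
    "LineageEmbedding",
    "GPResult",
    "embed_lineage",
    "correlation_integral",
    "default_radii",
    "gp_dimension",
    "surrogate_test",
]

MIN_POINTS = 30


@dataclass
class LineageEmbedding:
    """Standardized ancestor-chain point cloud plus rebuild context."""

    points: np.ndarray           # (n, m) z-scored coordinates
    cell_ids: list[str]          # id of the youngest member of each chain
    m: int
    variable: str
    records: pd.DataFrame = field(repr=False, default=None)
    forest: LineageForest = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class GPResult:
    variable: str
    m: int
    radii: np.ndarray
    c: np.ndarray
    nu: float
    surrogate_nu: np.ndarray
    quantile: float
    n_points: int

    @property
    def threshold(self) -> float:
        return float(np.percentile(self.surrogate_nu, 100 * self.quantile))

    @property
    def deterministic(self) -> bool:
        return bool(self.nu < self.threshold)

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "m": self.m,
            "nu": self.nu,
            "surrogate_nu_mean": float(np.mean(self.surrogate_nu)),
            "surrogate_nu_q": self.threshold,
            "quantile": self.quantile,
            "n_points": self.n_points,
            "n_surrogates": int(len(self.surrogate_nu)),
            "verdict": "deterministic" if self.deterministic else "stochastic",
        }


def _chain_values(records: pd.DataFrame, forest: LineageForest, col: str,
                  m: int) -> tuple[np.ndarray, list[str]]:
    val = {}
    for cid, v, comp in zip(
        records["cell_id"], records[col], records["complete"]
    ):
        if comp and np.isfinite(v):
            val[cid] = float(v)
    pts, ids = [], []
    for cid in sorted(val):
        chain = [cid]
        cur = cid
        ok = True
        for _ in range(m - 1):
            cur = forest.parent.get(cur, "")
            if cur not in val:
                ok = False
                break
            chain.append(cur)
        if ok:
            pts.append([val[c] for c in reversed(chain)])  # oldest first
            ids.append(cid)
    return np.asarray(pts, dtype=float), ids


def embed_lineage(
    records: pd.DataFrame,
    forest: LineageForest,
    variable: str = "g1_l",
    m: int = 3,
) -> LineageEmbedding:
    """One point per complete cell having m-1 complete ancestors with values."""
    if m not in (1, 2, 3):
        raise ValueError("embedding dimension m must be in {1, 2, 3}")
    col = VARIABLES[variable]
    pts, ids = _chain_values(records, forest, col, m)
    if len(pts):
        mu = pts.mean(axis=0)
        sd = pts.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        pts = (pts - mu) / sd
    return LineageEmbedding(
        points=pts, cell_ids=ids, m=m, variable=variable,
        records=records, forest=forest,
    )


def correlation_integral(
    points: np.ndarray, radii: np.ndarray, min_points: int = 2
) -> np.ndarray:
    """Exact pairwise correlation integral C(r) (Euclidean norm).

    ``C(r) = 2/(N(N-1)) * #{pairs i<j : ||x_i - x_j|| < r}``.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) < max(min_points, 2):
        raise ValueError(f"need >= {max(min_points, 2)} points, got {len(points)}")
    d = pdist(points)
    radii = np.asarray(radii, dtype=float)
    return np.searchsorted(np.sort(d), radii, side="left") / len(d)


def default_radii(points: np.ndarray, n: int = 30) -> np.ndarray:
    """Log-spaced radii spanning the pairwise-distance distribution."""
    d = pdist(np.atleast_2d(points))
    d = d[d > 0]
    lo = np.quantile(d, 0.005)
    hi = d.max() * 1.05
    return np.geomspace(lo, hi, n)


def gp_dimension(
    c: np.ndarray,
    radii: np.ndarray,
    fit_range: tuple[float, float] = (0.05, 0.5),
) -> float:
    """Scaling exponent: least-squares slope of log C vs log r.

    ``fit_range`` bounds C, defaulting to the usual intermediate scaling
    window 0.05 <= C <= 0.5.
    """
    c = np.asarray(c, dtype=float)
    radii = np.asarray(radii, dtype=float)
    lo, hi = fit_range
    if not (0 <= lo < hi <= 1):
        raise ValueError("degenerate fit range")
    mask = (c >= lo) & (c <= hi) & (c > 0) & (c < 1)
    if np.sum(mask) < 4:
        raise ValueError(
            f"only {int(np.sum(mask))} radii inside fit range (need >= 4)"
        )
    slope = np.polyfit(np.log(radii[mask]), np.log(c[mask]), 1)[0]
    return float(slope)


def _shuffled_records(records: pd.DataFrame, col: str,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Shuffle a variable across complete cells within (colony x generation)."""
    out = records.copy()
    usable = out["complete"] & np.isfinite(out[col])
    for _, idx in out.loc[usable].groupby(["colony_id", "generation"]).groups.items():
        idx = np.asarray(idx)
        out.loc[idx, col] = out.loc[rng.permutation(idx), col].to_numpy()
    return out


def surrogate_test(
    embedding: LineageEmbedding,
    n_surrogates: int = 100,
    seed: int = 0,
    radii: Optional[np.ndarray] = None,
    fit_range: tuple[float, float] = (0.05, 0.5),
    quantile: float = 0.05,
) -> GPResult:
    """Compare the data's scaling exponent against shuffle surrogates.

    Verdict is "deterministic" iff the data exponent falls below the
    ``quantile`` (default 5th percentile) of the surrogate exponents.
    """
    if len(embedding) < MIN_POINTS:
        raise ValueError(f"embedding has {len(embedding)} points (< {MIN_POINTS})")
    if embedding.records is None or embedding.forest is None:
        raise ValueError("embedding lacks rebuild context for surrogates")
    pts = embedding.points
    if radii is None:
        radii = default_radii(pts)
    c = correlation_integral(pts, radii)
    nu = gp_dimension(c, radii, fit_range)
    col = VARIABLES[embedding.variable]
    rng = np.random.default_rng(seed)
    sur = np.empty(n_surrogates)
    for i in range(n_surrogates):
        shuffled = _shuffled_records(embedding.records, col, rng)
        emb_s = embed_lineage(shuffled, embedding.forest, embedding.variable, embedding.m)
        c_s = correlation_integral(emb_s.points, radii)
        sur[i] = gp_dimension(c_s, radii, fit_range)
    return GPResult(
        variable=embedding.variable, m=embedding.m, radii=radii, c=c,
        nu=nu, surrogate_nu=sur, quantile=quantile, n_points=len(pts),
    )
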