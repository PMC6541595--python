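"""Lineage correlation analysis.

Raw pooled correlations between relatives are inflated by two nuisance
factors: generation drift (differentiating cells shorten their cycle every
generation) and colony identity (colonies differ in mean cycle length).
Pair values are therefore replaced by within-(condition x generation)
stratum ranks before correlating, and uncertainty comes from a two-level
bootstrap: colonies resampled with replacement, then pairs within the
resampled colonies.

The simple-inheritance comparison tests whether the cousin correlation
exceeds the product ``rho_md^2 * rho_sister`` implied by a memoryless
parent-to-daughter chain; the three coefficients share bootstrap
replicates (same colony resamples) so their difference has a valid
percentile CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import Relation
from .lineage import LineageForest, enumerate_pairs
from .survival import VARIABLES

__all__ = [
    "BootstrapCorr",
    "InheritanceVerdict",
    "spearman",
    "attach_values",
    "stratified_center",
    "bootstrap_corr",
    "bootstrap_relations",
    "inheritance_inequality",
]


def spearman(x, y) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with >= 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: Spearman correlation undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def attach_values(
    pairs: pd.DataFrame, records: pd.DataFrame, variable: str = "cc_l"
) -> pd.DataFrame:
    """Join the chosen cycle variable onto a pair table as value_a/value_b.

    Pairs where either member lacks the variable (e.g. uncallable G1) are
    dropped.
    """
    col = VARIABLES[variable]
    lookup = records.set_index("cell_id")[col]
    out = pairs.copy()
    out["value_a"] = lookup.reindex(out["cell_a"]).to_numpy()
    out["value_b"] = lookup.reindex(out["cell_b"]).to_numpy()
    out = out.loc[np.isfinite(out["value_a"]) & np.isfinite(out["value_b"])]
    return out.reset_index(drop=True)


def stratified_center(
    pairs: pd.DataFrame,
    method: str = "rank",
    symmetric: Optional[bool] = None,
) -> pd.DataFrame:
    """Remove stratum-level drift from pair values.

    Within each (condition x generation) stratum, values are replaced by
    normalized within-stratum ranks (``method="rank"``) or mean-centered
    (``method="mean"``). For exchangeable relations (sisters, cousins) the
    two pair members are pooled before ranking, so swapping a/b labels
    changes nothing; for mother-daughter pairs each role is centered
    separately, since the mother belongs to the previous generation.
    Strata with fewer than 2 pairs are dropped with a warning.
    """
    if method not in ("rank", "mean"):
        raise ValueError(f"unknown centering method {method!r}")
    if symmetric is None:
        rels = set(pairs["relation"].unique())
        symmetric = Relation.MOTHER_DAUGHTER.value not in rels
    out = []
    for (cond, gen), grp in pairs.groupby(["condition", "generation"], sort=True):
        if len(grp) < 2:
            warnings.warn(f"stratum ({cond}, gen {gen}) has {len(grp)} pair(s); dropped")
            continue
        grp = grp.copy()
        a = grp["value_a"].to_numpy(dtype=float)
        b = grp["value_b"].to_numpy(dtype=float)
        if method == "mean":
            if symmetric:
                m = np.mean(np.concatenate([a, b]))
                grp["value_a"], grp["value_b"] = a - m, b - m
            else:
                grp["value_a"], grp["value_b"] = a - a.mean(), b - b.mean()
        else:
            if symmetric:
                r = stats.rankdata(np.concatenate([a, b]))
                r = (r - 0.5) / len(r)
                grp["value_a"], grp["value_b"] = r[: len(a)], r[len(a):]
            else:
                grp["value_a"] = (stats.rankdata(a) - 0.5) / len(a)
                grp["value_b"] = (stats.rankdata(b) - 0.5) / len(b)
        out.append(grp)
    if not out:
        raise ValueError("no stratum with >= 2 pairs")
    return pd.concat(out, ignore_index=True)


@dataclass
class BootstrapCorr:
    relation: str
    variable: str
    rho_hat: float
    ci_low: float
    ci_high: float
    p_value: float
    n_pairs: int
    n_boot: int
    seed: int
    replicates: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "relation": self.relation,
            "variable": self.variable,
            "rho_hat": self.rho_hat,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n_pairs": self.n_pairs,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


def _fast_spearman(a: np.ndarray, b: np.ndarray) -> float:
    if np.all(a == a[0]) or np.all(b == b[0]):
        return float("nan")
    return float(np.corrcoef(stats.rankdata(a), stats.rankdata(b))[0, 1])


def _summarize(
    rho_hat: float, reps: np.ndarray, relation: str, variable: str,
    n_pairs: int, n_boot: int, seed: int,
) -> BootstrapCorr:
    ok = reps[np.isfinite(reps)]
    if len(ok) < n_boot:
        warnings.warn(f"{n_boot - len(ok)} degenerate bootstrap replicates dropped")
    lo, hi = np.percentile(ok, [2.5, 97.5])
    p = 2.0 * min(np.mean(ok <= 0), np.mean(ok >= 0))
    p = float(max(p, 1.0 / len(ok)))
    return BootstrapCorr(
        relation=relation, variable=variable, rho_hat=float(rho_hat),
        ci_low=float(lo), ci_high=float(hi), p_value=min(p, 1.0),
        n_pairs=n_pairs, n_boot=n_boot, seed=seed, replicates=reps,
    )


def bootstrap_corr(
    pairs: pd.DataFrame,
    variable: str = "cc_l",
    n_boot: int = 2000,
    seed: int = 0,
    center_method: str = "rank",
) -> BootstrapCorr:
    """Stratified-centered Spearman with a two-level cluster bootstrap.

    ``pairs`` must already carry value_a/value_b (see :func:`attach_values`).
    """
    if len(pairs) < 10:
        raise ValueError(f"need >= 10 pairs, got {len(pairs)}")
    centered = stratified_center(pairs, method=center_method)
    colonies = sorted(centered["colony_id"].unique())
    if len(colonies) < 2:
        raise ValueError("need >= 2 colonies to resample colonies")
    a = centered["value_a"].to_numpy(dtype=float)
    b = centered["value_b"].to_numpy(dtype=float)
    rho_hat = _fast_spearman(a, b)
    groups = [
        np.flatnonzero((centered["colony_id"] == c).to_numpy()) for c in colonies
    ]
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for i in range(n_boot):
        chosen = rng.integers(len(groups), size=len(groups))
        idx = np.concatenate([
            groups[g][rng.integers(len(groups[g]), size=len(groups[g]))]
            for g in chosen
        ])
        reps[i] = _fast_spearman(a[idx], b[idx])
    relation = pairs["relation"].iloc[0] if "relation" in pairs else ""
    return _summarize(rho_hat, reps, relation, variable, len(pairs), n_boot, seed)


def bootstrap_relations(
    records: pd.DataFrame,
    forest: LineageForest,
    variable: str = "cc_l",
    n_boot: int = 2000,
    seed: int = 0,
    relations: Sequence[Relation] = (
        Relation.SISTER, Relation.MOTHER_DAUGHTER, Relation.COUSIN,
    ),
    center_method: str = "rank",
) -> dict[Relation, BootstrapCorr]:
    """Bootstrap all relations on shared colony resamples.

    The shared replicate structure makes the per-replicate coefficients
    jointly resampled, as required by :func:`inheritance_inequality`.
    """
    rng = np.random.default_rng(seed)
    md_seed = int(rng.integers(2**31))  # dedicated stream for daughter choice
    centered: dict[Relation, pd.DataFrame] = {}
    for rel in relations:
        p = enumerate_pairs(forest, rel, require_complete=True, seed=md_seed)
        p = attach_values(p, records, variable)
        if len(p) < 10:
            raise ValueError(f"{rel.value}: only {len(p)} usable pairs (need >= 10)")
        centered[rel] = stratified_center(p, method=center_method)
    colonies = sorted(set().union(*(set(c["colony_id"]) for c in centered.values())))
    if len(colonies) < 2:
        raise ValueError("need >= 2 colonies to resample colonies")
    arrays = {}
    for rel, c in centered.items():
        a = c["value_a"].to_numpy(dtype=float)
        b = c["value_b"].to_numpy(dtype=float)
        groups = {
            col: np.flatnonzero((c["colony_id"] == col).to_numpy()) for col in colonies
        }
        arrays[rel] = (a, b, groups)
    reps = {rel: np.empty(n_boot) for rel in centered}
    for i in range(n_boot):
        chosen = [colonies[j] for j in rng.integers(len(colonies), size=len(colonies))]
        for rel, (a, b, groups) in arrays.items():
            parts = []
            for colname in chosen:
                g = groups[colname]
                if len(g):
                    parts.append(g[rng.integers(len(g), size=len(g))])
            if parts:
                idx = np.concatenate(parts)
                reps[rel][i] = _fast_spearman(a[idx], b[idx]) if len(idx) >= 3 else np.nan
            else:
                reps[rel][i] = np.nan
    out = {}
    for rel, (a, b, groups) in arrays.items():
        rho_hat = _fast_spearman(a, b)
        out[rel] = _summarize(
            rho_hat, reps[rel], rel.value, variable,
            len(centered[rel]), n_boot, seed,
        )
    return out


@dataclass
class InheritanceVerdict:
    """Replicate-wise test of cousin correlation vs the simple-inheritance product."""

    delta_hat: float  # rho_cc - rho_md^2 * rho_ss
    ci_low: float
    ci_high: float
    exceeds_simple_inheritance: bool
    n_boot: int

    def to_dict(self) -> dict:
        return {
            "delta_hat": self.delta_hat,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "exceeds_simple_inheritance": self.exceeds_simple_inheritance,
            "n_boot": self.n_boot,
        }


def inheritance_inequality(
    ss: BootstrapCorr, md: BootstrapCorr, cc: BootstrapCorr
) -> InheritanceVerdict:
    """Percentile CI on ``rho_cc - rho_md^2 * rho_ss`` from joint replicates."""
    for x in (ss, md, cc):
        if x.replicates is None:
            raise ValueError("BootstrapCorr objects must carry replicates")
    if not (len(ss.replicates) == len(md.replicates) == len(cc.replicates)):
        raise ValueError("mismatched replicate counts: need joint resampling")
    delta = cc.replicates - md.replicates**2 * ss.replicates
    ok = delta[np.isfinite(delta)]
    lo, hi = np.percentile(ok, [2.5, 97.5])
    delta_hat = cc.rho_hat - md.rho_hat**2 * ss.rho_hat
    return InheritanceVerdict(
        delta_hat=float(delta_hat), ci_low=float(lo), ci_high=float(hi),
        exceeds_simple_inheritance=bool(lo > 0),
        n_boot=len(ss.replicates),
    )
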