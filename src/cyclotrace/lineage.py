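"""Lineage forests and relative-pair enumeration.

Sister pairs come one per division (both daughters complete when
``require_complete``); mother-daughter pairs pick one complete daughter per
complete parent uniformly at random with a dedicated seeded RNG, so
correlation analyses are reproducible; cousin pairs are all cross
combinations of complete granddaughters through different daughters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import Relation
from .extraction import assign_generations

__all__ = ["LineageForest", "build_forest", "enumerate_pairs"]

PAIR_COLUMNS = [
    "relation", "cell_a", "cell_b", "colony_id", "condition", "generation",
]


@dataclass
class LineageForest:
    """Parent/child structure over all cells, with records joined by id."""

    parent: dict[str, str]
    children: dict[str, list[str]]
    colony: dict[str, str]
    records: pd.DataFrame  # indexed by cell_id

    @property
    def roots(self) -> list[str]:
        return [c for c, p in self.parent.items() if not p]

    def __len__(self) -> int:
        return len(self.parent)


def build_forest(records: pd.DataFrame) -> LineageForest:
    """Build a forest from a record table (validated parent links).

    Raises on ancestry cycles or cross-colony parentage; generation labels
    are recomputed from the links and must match the records.
    """
    idx = records.set_index("cell_id", drop=False)
    if idx.index.duplicated().any():
        dupes = idx.index[idx.index.duplicated()].tolist()
        raise ValueError(f"duplicate cell ids: {dupes[:5]}")
    parent: dict[str, str] = {}
    children: dict[str, list[str]] = {c: [] for c in idx.index}
    colony = idx["colony_id"].to_dict()
    for cid, pid in idx["parent_id"].items():
        pid = "" if pd.isna(pid) else str(pid)
        parent[cid] = pid
        if pid:
            if pid not in children:
                raise ValueError(f"cell {cid} references unknown parent {pid}")
            if colony[pid] != colony[cid]:
                raise ValueError(f"cross-colony parentage: {cid} <- {pid}")
            children[pid].append(cid)
    assign_generations(parent)  # raises on cycles
    return LineageForest(parent=parent, children=children, colony=colony, records=idx)


def enumerate_pairs(
    forest: LineageForest,
    relation: Relation | str,
    require_complete: bool = True,
    seed: int = 0,
    cousin_sample_one: bool = False,
) -> pd.DataFrame:
    """Enumerate relative pairs of one relation as a tidy table.

    Each pair appears once (never in both orders); its generation stratum
    is the generation of the younger member. Cells flagged ``track_gap``
    never enter pairs.
    """
    relation = Relation(relation)
    rec = forest.records
    usable = set(rec.index[~rec["track_gap"]])
    if require_complete:
        usable &= set(rec.index[rec["complete"]])

    def gen(cid: str) -> int:
        return int(rec.at[cid, "generation"])

    def cond(cid: str) -> str:
        return str(rec.at[cid, "condition"])

    rows = []
    rng = np.random.default_rng(seed)
    if relation is Relation.SISTER:
        for pid, kids in sorted(forest.children.items()):
            if len(kids) == 2 and all(k in usable for k in kids):
                a, b = sorted(kids)
                rows.append((relation.value, a, b, forest.colony[a], cond(a), gen(a)))
    elif relation is Relation.MOTHER_DAUGHTER:
        for pid in sorted(forest.children):
            if pid not in usable:
                continue
            kids = [k for k in sorted(forest.children[pid]) if k in usable]
            if not kids:
                continue
            k = kids[int(rng.integers(len(kids)))]
            rows.append((relation.value, pid, k, forest.colony[pid], cond(k), gen(k)))
    elif relation is Relation.COUSIN:
        for gp, kids in sorted(forest.children.items()):
            if len(kids) != 2:
                continue
            side_a = [c for c in sorted(forest.children.get(kids[0], [])) if c in usable]
            side_b = [c for c in sorted(forest.children.get(kids[1], [])) if c in usable]
            cross = [(a, b) for a in side_a for b in side_b]
            if not cross:
                continue
            if cousin_sample_one:
                cross = [cross[int(rng.integers(len(cross)))]]
            for a, b in cross:
                a2, b2 = sorted((a, b))
                rows.append(
                    (relation.value, a2, b2, forest.colony[a2], cond(a2),
                     max(gen(a2), gen(b2)))
                )
    else:  # pragma: no cover - Relation() above already rejects
        raise ValueError(f"unknown relation {relation}")
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)
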