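import dataclasses

import numpy as np
import pandas as pd
import pytest

from cyclotrace.datamodel import Condition, RECORD_COLUMNS
from cyclotrace.extraction import extract_records
from cyclotrace.synthetic import default_params, simulate_lineage


@pytest.fixture(scope="session")
def small_params():
    return default_params(seed=11, n_colonies=3, n_founders=3)


@pytest.fixture(scope="session")
def ground_table(small_params):
    return simulate_lineage(small_params, Condition.GROUND_STATE)


@pytest.fixture(scope="session")
def ground_records(ground_table):
    return extract_records(ground_table)


@pytest.fixture(scope="session")
def diff_table(small_params):
    return simulate_lineage(small_params, Condition.DIFF)


def make_records(rows):
    """Hand-built record table; rows are dicts with cell_id/parent_id plus overrides."""
    out = []
    for r in rows:
        base = {
            "cell_id": r["cell_id"],
            "colony_id": r.get("colony_id", "C0"),
            "condition": r.get("condition", Condition.GROUND_STATE.value),
            "parent_id": r.get("parent_id", ""),
            "generation": r.get("generation", 1),
            "birth_time_h": r.get("birth_time_h", np.nan),
            "end_time_h": r.get("end_time_h", 10.0),
            "fate": r.get("fate", "DIVIDED"),
            "cc_l_h": r.get("cc_l_h", np.nan),
            "g1_l_h": r.get("g1_l_h", np.nan),
            "sg2m_l_h": r.get("sg2m_l_h", np.nan),
            "complete": r.get("complete", False),
            "track_gap": r.get("track_gap", False),
        }
        out.append(base)
    return pd.DataFrame(out, columns=RECORD_COLUMNS)


def full_binary_tree_records(depth=3, colony="C0", complete=True, values=None):
    """Records for a full binary tree: 2^depth - 1 cells, ids n1..; n1 is root.

    All cells are marked complete (including the root) so pair-enumeration
    examples behave like the textbook tree; ``values`` optionally maps
    cell index -> cc_l_h.
    """
    rows = []
    n = 2**depth - 1
    for i in range(1, n + 1):
        gen = i.bit_length()
        parent = f"n{i // 2}" if i > 1 else ""
        cc = values.get(i) if values else 10.0 + i * 0.25
        rows.append({
            "cell_id": f"n{i}",
            "colony_id": colony,
            "parent_id": parent,
            "generation": gen,
            "birth_time_h": 1.0 * gen,
            "end_time_h": 1.0 * gen + cc,
            "cc_l_h": cc,
            "g1_l_h": cc * 0.3,
            "sg2m_l_h": cc * 0.7,
            "complete": complete,
            "fate": "DIVIDED",
        })
    return make_records(rows)


@pytest.fixture
def tree7():
    return full_binary_tree_records(depth=3)


def no_censoring_params(seed=0, n_colonies=8, n_founders=2, max_cells=250, **cond_kw):
    """Deep trees, negligible censoring: growth stopped by the cell cap."""
    base = default_params(seed=seed, n_colonies=n_colonies, n_founders=n_founders)
    cp = dataclasses.replace(
        base.conditions[Condition.GROUND_STATE],
        apoptosis_prob=0.0, track_loss_scale=0.0, **cond_kw,
    )
    return dataclasses.replace(
        base,
        conditions={Condition.GROUND_STATE: cp},
        window_h=500.0,
        max_cells_per_colony=max_cells,
    )
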