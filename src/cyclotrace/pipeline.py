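"""End-to-end orchestration: simulate/ingest -> extract -> lineage ->
survival -> correlation -> determinism -> motility, with per-stage seeds
fanned out from one master seed and a machine-readable report bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd

from . import __version__
from .datamodel import Condition, DatasetMetadata, Fate, Relation
from .io_tracking import read_tracking_table, write_database
from .extraction import extract_records
from .lineage import build_forest
from .survival import km_inputs, km_estimate, generation_fraction
from .correlation import bootstrap_relations, inheritance_inequality
from .determinism import embed_lineage, surrogate_test, MIN_POINTS
from .motility import (
    classify_peripheral,
    colony_metrics,
    motility_summary,
    nuclear_area_summary,
)
from .synthetic import (
    SimulationParams,
    apoptosis_overrides,
    default_params,
    simulate_dataset,
)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Validated knobs for every stage of the pipeline."""

    seed: int = 0
    simulation: Optional[SimulationParams] = None  # None -> read input_table
    input_table: Optional[str] = None
    metadata: DatasetMetadata = field(default_factory=DatasetMetadata)
    variables: tuple[str, ...] = ("cc_l", "g1_l", "sg2m_l")
    n_boot: int = 2000
    km_min_stratum: int = 10
    gp_variables: tuple[str, ...] = ("g1_l", "sg2m_l")
    gp_m: tuple[int, ...] = (2, 3)
    gp_surrogates: int = 100
    smooth_window: int = 3
    prominence_frac: float = 0.10

    def __post_init__(self) -> None:
        if self.simulation is None and self.input_table is None:
            self.simulation = default_params(seed=self.seed)
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.km_min_stratum < 1:
            raise ValueError("km_min_stratum must be >= 1")
        for m in self.gp_m:
            if m not in (1, 2, 3):
                raise ValueError("gp_m entries must be in {1, 2, 3}")

    def to_jsonable(self) -> dict:
        d: dict[str, Any] = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"]["conditions"] = {
                k.value: dataclasses.asdict(v)
                for k, v in self.simulation.conditions.items()
            }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_jsonable(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir: str | os.PathLike) -> dict:
    """Run every stage, writing the report bundle into ``outdir``.

    Returns the run manifest (also written as ``manifest.json``).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "cyclotrace_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }

    # --- stage 1: input table -------------------------------------------
    if config.simulation is not None:
        params = dataclasses.replace(config.simulation, seed=config.seed)
        table = simulate_dataset(params)
        overrides = apoptosis_overrides(table.truth)
        metadata = params.metadata
    else:
        metadata = config.metadata
        table = read_tracking_table(config.input_table, metadata)
        overrides = None
    manifest["stages"]["input"] = {
        "n_rows": len(table.df),
        "n_cells": len(table.cells()),
        "n_violations": len(table.violations),
    }

    # --- stage 2: extraction --------------------------------------------
    records = extract_records(
        table, metadata, overrides=overrides,
        smooth_window=config.smooth_window,
        prominence_frac=config.prominence_frac,
    )
    write_database(records, out / "records.csv")
    counts = {}
    for cond in records["condition"].unique():
        r = records.loc[records["condition"] == cond]
        counts[cond] = {
            "tracked": len(r),
            "complete": int(r["complete"].sum()),
            "censored_end": int((r["fate"] == Fate.CENSORED_END.value).sum()),
            "track_lost": int((r["fate"] == Fate.TRACK_LOST.value).sum()),
            "apoptosis": int((r["fate"] == Fate.APOPTOSIS.value).sum()),
            "generation5_pct": generation_fraction(r, 5),
        }
    manifest["stages"]["extraction"] = counts

    forest = build_forest(records)

    # --- stage 3: survival ----------------------------------------------
    km_rows = []
    for cond in sorted(records["condition"].unique()):
        sub = records.loc[records["condition"] == cond]
        for var in config.variables:
            inputs = km_inputs(sub, var)
            for gen, grp in inputs.groupby("generation"):
                if len(grp) < config.km_min_stratum:
                    continue
                curve = km_estimate(
                    grp["duration"], grp["observed"],
                    label=f"{cond}|{var}|gen{int(gen)}",
                )
                km_rows.append(curve.to_frame())
    km_df = (
        pd.concat(km_rows, ignore_index=True)
        if km_rows
        else pd.DataFrame(columns=["stratum", "t", "S", "n_at_risk", "d"])
    )
    km_df.to_csv(out / "km.csv", index=False)
    manifest["stages"]["survival"] = {"n_strata": int(km_df["stratum"].nunique())}

    # --- stage 4: correlation -------------------------------------------
    corr_report: dict[str, Any] = {}
    boot_seed = _stage_seed(config.seed, "bootstrap")
    for cond in sorted(records["condition"].unique()):
        sub = records.loc[records["condition"] == cond].reset_index(drop=True)
        sub_forest = build_forest(sub)
        corr_report[cond] = {}
        for var in config.variables:
            try:
                boot = bootstrap_relations(
                    sub, sub_forest, var,
                    n_boot=config.n_boot, seed=boot_seed,
                )
                entry = {rel.value: bc.to_dict() for rel, bc in boot.items()}
                entry["inheritance_inequality"] = inheritance_inequality(
                    boot[Relation.SISTER],
                    boot[Relation.MOTHER_DAUGHTER],
                    boot[Relation.COUSIN],
                ).to_dict()
            except ValueError as exc:
                entry = {"error": str(exc)}
            corr_report[cond][var] = entry
    (out / "corr.json").write_text(
        json.dumps(corr_report, indent=2, default=_json_default)
    )
    manifest["stages"]["correlation"] = {"seed": boot_seed}

    # --- stage 5: determinism -------------------------------------------
    gp_report: dict[str, Any] = {}
    gp_seed = _stage_seed(config.seed, "gp_surrogates")
    for cond in sorted(records["condition"].unique()):
        sub = records.loc[records["condition"] == cond].reset_index(drop=True)
        sub_forest = build_forest(sub)
        gp_report[cond] = {}
        for var in config.gp_variables:
            gp_report[cond][var] = {}
            for m in config.gp_m:
                emb = embed_lineage(sub, sub_forest, var, m)
                if len(emb) < MIN_POINTS:
                    gp_report[cond][var][f"m{m}"] = {
                        "error": f"only {len(emb)} points (< {MIN_POINTS})"
                    }
                    continue
                res = surrogate_test(
                    emb, n_surrogates=config.gp_surrogates, seed=gp_seed
                )
                gp_report[cond][var][f"m{m}"] = res.to_dict()
    (out / "gp.json").write_text(
        json.dumps(gp_report, indent=2, default=_json_default)
    )
    manifest["stages"]["determinism"] = {"seed": gp_seed}

    # --- stage 6: motility ----------------------------------------------
    peripheral = classify_peripheral(table)
    mot = motility_summary(records, table, peripheral=peripheral)
    mot.to_csv(out / "motility.csv", index=False)
    colony = colony_metrics(table)
    colony.to_csv(out / "colony.csv", index=False)
    areas = nuclear_area_summary(table, records)
    areas.to_csv(out / "nuclear_area.csv", index=False)
    manifest["stages"]["motility"] = {
        "n_cells": len(mot),
        "n_colony_frames": len(colony),
    }

    artifacts = [
        "records.csv", "km.csv", "corr.json", "gp.json",
        "motility.csv", "colony.csv", "nuclear_area.csv",
    ]
    manifest["artifact_hashes"] = {a: _file_hash(out / a) for a in artifacts}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=_json_default)
    )
    return manifest


def load_config(path: str | os.PathLike) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file.

    Recognized top-level keys mirror the dataclass fields; a ``simulation``
    block maps onto :class:`SimulationParams` with per-condition
    sub-blocks under ``conditions``.
    """
    import yaml

    from .synthetic import ConditionParams

    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict[str, Any] = {}
    for key in (
        "seed", "input_table", "n_boot", "km_min_stratum",
        "gp_surrogates", "smooth_window", "prominence_frac",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    for key in ("variables", "gp_variables", "gp_m"):
        if key in raw:
            kwargs[key] = tuple(raw[key])
    if "metadata" in raw:
        kwargs["metadata"] = DatasetMetadata(**raw["metadata"])
    if "simulation" in raw:
        sim = dict(raw["simulation"])
        conds = {
            Condition.parse(k): ConditionParams(**v)
            for k, v in sim.pop("conditions", {}).items()
        }
        base = default_params()
        merged = dict(base.conditions)
        merged.update(conds)
        kwargs["simulation"] = SimulationParams(conditions=merged, **sim)
    return PipelineConfig(**kwargs)
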