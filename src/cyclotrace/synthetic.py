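"""Synthetic lineage generator.

Produces per-frame tracking tables with the statistical structure the
downstream analyses assume: heritable log-normal G1 / S-G2-M durations with
strong sister and weak mother-daughter correlation, optional per-generation
shortening, rare apoptosis, two-channel fluorescence traces peaking at the
G1/S boundary, and colony-confined 2D motion. The generative truth (phase
lengths, generation, fate) is emitted alongside so extraction accuracy can
be scored.

Inheritance model
-----------------
Each cell carries a standard-normal inheritance score evolving down the
tree as an AR(1)-type kernel with a division-shared term::

    x_child = alpha * x_parent + gamma * x_grandparent
              + s * h_division + c * eps_child

where ``h_division`` is shared by the two sisters. Two modes are offered:

* ``"latent"`` (default): one score per cell; each phase's log-duration
  loads on it with weight ``w_v`` plus independent noise, chosen so sister
  and mother-daughter correlations hit their targets. Measurement noise
  (``w_v < 1``) makes cousin correlation exceed the simple-inheritance
  product — the generic situation.
* ``"direct"``: each phase's log-duration normal score *is* its own kernel
  (no extra noise), in which case ``rho_cousin = rho_md^2 * rho_sister``
  holds exactly — the simple-inheritance null model.

``gamma > 0`` adds an explicit grandmother-shared component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .datamodel import (
    RECORD_COLUMNS,
    Condition,
    DatasetMetadata,
    Fate,
    TrackingTable,
)

__all__ = [
    "ConditionParams",
    "SimulationParams",
    "default_params",
    "simulate_lineage",
    "simulate_truth",
    "simulate_dataset",
    "ground_truth",
    "apoptosis_overrides",
]


@dataclass(frozen=True)
class ConditionParams:
    """Per-condition generative parameters."""

    median_g1_h: float = 3.45
    median_sg2m_h: float = 10.05
    sigma_log_g1: float = 0.25
    sigma_log_sg2m: float = 0.16
    per_generation_shrink: float = 1.0
    sister_rho_g1: float = 0.8
    sister_rho_sg2m: float = 0.5
    md_rho: float = 0.2
    inheritance_mode: str = "latent"  # "latent" | "direct"
    grandmother_weight: float = 0.0
    apoptosis_prob: float = 0.03
    founder_age_max_frac: float = 0.35
    gen1_median_scale: float = 1.1   # founders cycle at pre-imaging speed
    track_loss_scale: float = 0.4    # crowding loss: P = scale*(birth/window)^2
    step_scale: float = 0.8
    persistence: float = 0.5
    colony_attraction: float = 0.03  # negative = outward dispersal
    division_jump: float = 3.0
    area_median: float = 120.0
    fluor_noise_sd: float = 0.05  # fraction of peak amplitude
    peak_jitter_frames: float = 1.0

    def __post_init__(self) -> None:
        if self.median_g1_h <= 0 or self.median_sg2m_h <= 0:
            raise ValueError("phase medians must be > 0")
        if not (0 < self.per_generation_shrink <= 1):
            raise ValueError("per_generation_shrink must be in (0, 1]")
        for r in (self.sister_rho_g1, self.sister_rho_sg2m, self.md_rho):
            if not (0 <= r < 1):
                raise ValueError("correlations must be in [0, 1)")
        if not (0 <= self.apoptosis_prob < 1):
            raise ValueError("apoptosis_prob must be in [0, 1)")
        if self.inheritance_mode not in ("latent", "direct"):
            raise ValueError(f"unknown inheritance_mode {self.inheritance_mode!r}")


@dataclass(frozen=True)
class SimulationParams:
    """Global simulation parameters; one RNG stream per (condition, colony)."""

    seed: int = 0
    n_colonies: int = 4
    n_founders: int = 3
    window_h: float = 45.0
    frame_interval_h: float = 0.25
    conditions: dict[Condition, ConditionParams] = field(default_factory=dict)
    max_cells_per_colony: int = 4000
    colony_spacing: float = 400.0

    def condition_params(self, condition: Condition) -> ConditionParams:
        return self.conditions.get(condition, ConditionParams())

    @property
    def metadata(self) -> DatasetMetadata:
        return DatasetMetadata(
            frame_interval_h=self.frame_interval_h, window_h=self.window_h
        )


def default_params(seed: int = 0, n_colonies: int = 4, n_founders: int = 3) -> SimulationParams:
    """Defaults emulating the two culture conditions of the study design.

    Ground state: median cycle ~13.3 h, generation-independent, ~3%
    apoptosis, cohesive colonies. Diff: generation-2 median cycle ~12 h
    shrinking 7.5% per generation, ~1% apoptosis, dispersing colonies with
    faster motion and larger nuclei.
    """
    ground = ConditionParams()
    diff = ConditionParams(
        median_g1_h=3.08,
        median_sg2m_h=8.92,
        per_generation_shrink=0.925,
        apoptosis_prob=0.01,
        gen1_median_scale=1.25,
        track_loss_scale=1.1,
        step_scale=1.2,
        colony_attraction=-0.008,
        area_median=156.0,
    )
    return SimulationParams(
        seed=seed,
        n_colonies=n_colonies,
        n_founders=n_founders,
        conditions={Condition.GROUND_STATE: ground, Condition.DIFF: diff},
    )


# --------------------------------------------------------------------------
# inheritance kernel


@dataclass(frozen=True)
class _Kernel:
    mode: str
    alpha: float
    gamma: float
    s: float  # division-shared weight
    c: float  # individual-noise weight
    w_g1: float  # latent loading per phase (latent mode; 1.0 in direct mode)
    w_sg2m: float


def _build_kernel(cp: ConditionParams) -> _Kernel:
    gamma = cp.grandmother_weight
    if cp.inheritance_mode == "direct":
        # per-variable chains share alpha/s so identities hold for both
        alpha = cp.md_rho
        r_s = max(cp.sister_rho_g1, alpha**2)
        s2 = r_s - alpha**2
        c2 = max(1.0 - r_s - gamma**2, 0.02)
        return _Kernel("direct", alpha, gamma, math.sqrt(s2), math.sqrt(c2), 1.0, 1.0)
    r_s = min(0.97, max(cp.sister_rho_g1, cp.sister_rho_sg2m, 1e-12) + 0.05)
    w2_g1 = cp.sister_rho_g1 / r_s
    w2_sg2m = cp.sister_rho_sg2m / r_s
    w2_max = max(w2_g1, w2_sg2m, 1e-12)
    alpha = cp.md_rho / w2_max
    if alpha**2 > r_s:
        raise ValueError("md_rho too large relative to sister correlations")
    s2 = r_s - alpha**2
    c2 = max(1.0 - r_s - gamma**2, 0.02)
    return _Kernel(
        "latent", alpha, gamma, math.sqrt(s2), math.sqrt(c2),
        math.sqrt(w2_g1), math.sqrt(w2_sg2m),
    )


class _Cell:
    __slots__ = (
        "cell_id", "colony_id", "parent_id", "generation", "birth_true",
        "first_frame", "last_frame", "fate", "g1_true", "cc_true",
        "boundary_frame", "scores",
    )

    def __init__(self, **kw):
        for k, v in kw.items():
            setattr(self, k, v)


def _draw_scores(kern: _Kernel, rng: np.random.Generator,
                 parent: Optional[np.ndarray], grand: Optional[np.ndarray],
                 shared: np.ndarray) -> np.ndarray:
    """Advance the inheritance score(s) one generation.

    ``scores`` is a length-1 array in latent mode, length-2 (one chain per
    phase) in direct mode; ``shared`` has matching length and is common to
    both daughters of a division.
    """
    k = len(shared)
    if parent is None:
        return rng.standard_normal(k)
    g = grand if grand is not None else np.zeros(k)
    eps = rng.standard_normal(k)
    out = kern.alpha * parent + kern.gamma * g + kern.s * shared + kern.c * eps
    return out


def _phase_durations(cp: ConditionParams, kern: _Kernel, scores: np.ndarray,
                     generation: int, rng: np.random.Generator) -> tuple[float, float]:
    shrink = cp.per_generation_shrink ** max(generation - 2, 0)
    if generation == 1:
        shrink = cp.gen1_median_scale
    med_g1 = cp.median_g1_h * shrink
    med_sg2m = cp.median_sg2m_h * shrink
    if kern.mode == "direct":
        t_g1, t_sg2m = scores[0], scores[1]
    else:
        x = scores[0]
        t_g1 = kern.w_g1 * x + math.sqrt(max(1 - kern.w_g1**2, 0.0)) * rng.standard_normal()
        t_sg2m = kern.w_sg2m * x + math.sqrt(max(1 - kern.w_sg2m**2, 0.0)) * rng.standard_normal()
    g1 = med_g1 * math.exp(cp.sigma_log_g1 * t_g1)
    sg2m = med_sg2m * math.exp(cp.sigma_log_sg2m * t_sg2m)
    return g1, sg2m


# --------------------------------------------------------------------------
# colony simulation


def _simulate_colony(params: SimulationParams, condition: Condition,
                     colony_index: int) -> list[_Cell]:
    cp = params.condition_params(condition)
    kern = _build_kernel(cp)
    dt = params.frame_interval_h
    final_frame = params.metadata.n_frames - 1
    cond_code = 0 if condition is Condition.GROUND_STATE else 1
    rng = np.random.default_rng([params.seed, cond_code, colony_index])
    colony_id = f"{'G' if cond_code == 0 else 'D'}{colony_index:03d}"
    k_scores = 2 if kern.mode == "direct" else 1

    cells: list[_Cell] = []
    counter = 0
    # queue entries: (parent_cell or None, grand_scores or None, shared, birth_true)
    queue: list[tuple] = []
    for _ in range(params.n_founders):
        queue.append((None, None, np.zeros(k_scores), None))

    while queue:
        parent, grand_scores, shared, birth = queue.pop(0)
        if parent is None:
            scores = _draw_scores(kern, rng, None, None, shared)
            generation = 1
            parent_id = ""
        else:
            scores = _draw_scores(kern, rng, parent.scores, grand_scores, shared)
            generation = parent.generation + 1
            parent_id = parent.cell_id
        g1, sg2m = _phase_durations(cp, kern, scores, generation, rng)
        cc = g1 + sg2m
        if parent is None:
            # founders resume cycling early in their cycle after the medium
            # change that starts imaging, so observed depth stays realistic
            age0 = rng.uniform(0.0, min(cp.founder_age_max_frac, 0.999)) * cc
            birth = -age0
            first_frame = 0
        else:
            first_frame = parent.last_frame + 1
        t_end = birth + cc
        apoptotic = rng.uniform() < cp.apoptosis_prob
        p_loss = min(cp.track_loss_scale * (max(birth, 0.0) / params.window_h) ** 2, 0.9)
        lost = (not apoptotic) and rng.uniform() < p_loss
        if apoptotic or lost:
            t_end = birth + (0.2 + 0.8 * rng.uniform()) * cc

        counter += 1
        cell = _Cell(
            cell_id=f"{colony_id}c{counter:05d}",
            colony_id=colony_id,
            parent_id=parent_id,
            generation=generation,
            birth_true=birth,
            first_frame=first_frame,
            last_frame=final_frame,
            fate=Fate.CENSORED_END,
            g1_true=g1,
            cc_true=cc,
            boundary_frame=int(round((birth + g1) / dt)),
            scores=scores,
        )

        if t_end >= params.window_h - 1e-12:
            cell.fate = Fate.CENSORED_END
            cell.last_frame = final_frame
        else:
            cell.last_frame = max(int(math.floor(t_end / dt)), first_frame)
            if apoptotic:
                cell.fate = Fate.APOPTOSIS
            elif lost:
                cell.fate = Fate.TRACK_LOST
            elif len(cells) + len(queue) + 2 > params.max_cells_per_colony:
                # growth cap reached: record as a lost track, no daughters
                cell.fate = Fate.TRACK_LOST
            else:
                cell.fate = Fate.DIVIDED
                h = rng.standard_normal(k_scores)
                g_scores = parent.scores if parent is not None else None
                for _ in range(2):
                    queue.append((cell, g_scores, h, t_end))
        cells.append(cell)
    return cells


def _clamp_boundary(j: int, first_frame: int, last_frame: int) -> int:
    """Clamp a boundary frame to the interior of a cell's observed life.

    Interior placement (never the first or last frame) keeps the rendered
    peak a genuine local maximum; truth and rendering share this rule so
    noise-free extraction is exact.
    """
    if last_frame - first_frame >= 2:
        return min(max(j, first_frame + 1), last_frame - 1)
    return min(max(j, first_frame), last_frame)


def _truth_frame(cells: list[_Cell], params: SimulationParams,
                 condition: Condition) -> pd.DataFrame:
    dt = params.frame_interval_h
    rows = []
    parent_last = {c.cell_id: c.last_frame for c in cells}
    for c in cells:
        if c.parent_id:
            k = parent_last[c.parent_id]
            birth = (k + 0.5) * dt
        else:
            k = None
            birth = float("nan")
        divided = c.fate is Fate.DIVIDED
        end = (c.last_frame + 0.5) * dt if divided else c.last_frame * dt
        complete = divided and c.parent_id != ""
        cc = (c.last_frame - k) * dt if complete else float("nan")
        if complete:
            j = _clamp_boundary(c.boundary_frame, c.first_frame, c.last_frame)
            g1 = (j - k) * dt
            sg2m = cc - g1
        else:
            g1 = sg2m = float("nan")
        rows.append({
            "cell_id": c.cell_id,
            "colony_id": c.colony_id,
            "condition": condition.value,
            "parent_id": c.parent_id,
            "generation": c.generation,
            "birth_time_h": birth,
            "end_time_h": end,
            "fate": c.fate.value,
            "cc_l_h": cc,
            "g1_l_h": g1,
            "sg2m_l_h": sg2m,
            "complete": complete,
            "track_gap": False,
            "boundary_frame": c.boundary_frame,
            "true_cc_h": c.cc_true,   # continuous draws, known even when censored
            "true_g1_h": c.g1_true,
        })
    return pd.DataFrame(
        rows, columns=RECORD_COLUMNS + ["boundary_frame", "true_cc_h", "true_g1_h"]
    )


def _render_colony(cells: list[_Cell], params: SimulationParams,
                   condition: Condition, colony_index: int) -> pd.DataFrame:
    """Render per-frame fluorescence, position and area traces for a colony."""
    cp = params.condition_params(condition)
    dt = params.frame_interval_h
    cond_code = 0 if condition is Condition.GROUND_STATE else 1
    rng = np.random.default_rng([params.seed, cond_code, colony_index, 7919])
    n_side = max(int(math.ceil(math.sqrt(params.n_colonies))), 1)
    center = np.array([
        (colony_index % n_side) * params.colony_spacing,
        (colony_index // n_side) * params.colony_spacing,
    ])
    amp = 100.0
    base = 5.0
    last_pos: dict[str, np.ndarray] = {}
    last_vel: dict[str, np.ndarray] = {}
    frames_out = []
    for c in cells:
        nf = c.last_frame - c.first_frame + 1
        f = np.arange(c.first_frame, c.last_frame + 1)
        t = f * dt

        # --- fluorescence ---------------------------------------------
        jitter = int(round(rng.normal(0.0, cp.peak_jitter_frames))) if cp.peak_jitter_frames > 0 else 0
        j_raw = c.boundary_frame + jitter
        kb = int(round(c.birth_true / dt))  # may precede the window for founders
        cherry = np.empty(nf)
        if j_raw < c.first_frame and c.parent_id == "":
            # founder whose G1/S boundary precedes the window: pure decay
            j = j_raw
            tau = max((c.last_frame - c.first_frame) / 2.0, 1.0)
            cherry[:] = amp * np.exp(-(f - c.first_frame) / tau)
        else:
            j = _clamp_boundary(j_raw, c.first_frame, c.last_frame)
            rise = f <= j
            span = max(j - kb, 1)
            cherry[rise] = amp * (0.15 + 0.85 * (f[rise] - kb) / span)
            # decay fast enough that 3-frame smoothing cannot move the peak
            tau = max((c.last_frame - j) / 3.0, 1.0)
            cherry[~rise] = amp * np.exp(-(f[~rise] - j) / tau)
        venus = np.where(
            f <= j, 0.05 * amp,
            0.05 * amp + 0.95 * amp * (f - j) / max(c.last_frame - j + 1, 1),
        )
        if cp.fluor_noise_sd > 0:
            cherry = cherry + rng.normal(0, cp.fluor_noise_sd * amp, nf)
            venus = venus + rng.normal(0, cp.fluor_noise_sd * amp, nf)
        cherry = np.maximum(cherry + base, 0.0)
        venus = np.maximum(venus + base, 0.0)

        # --- position: persistent walk with radial colony force ------
        if c.parent_id and c.parent_id in last_pos:
            pos0 = last_pos[c.parent_id] + rng.normal(0, cp.division_jump, 2)
            vel0 = last_vel[c.parent_id] * 0.5
        else:
            pos0 = center + rng.normal(0, 5.0, 2)
            vel0 = np.zeros(2)
        steps = rng.normal(0, cp.step_scale, (nf, 2))
        xy = np.empty((nf, 2))
        pos, vel = pos0.copy(), vel0.copy()
        for i in range(nf):
            vel = cp.persistence * vel + steps[i] + cp.colony_attraction * (center - pos)
            pos = pos + vel
            xy[i] = pos
        last_pos[c.cell_id] = pos
        last_vel[c.cell_id] = vel

        area_cell = cp.area_median * math.exp(rng.normal(0, 0.1))
        area = np.maximum(area_cell * (1 + rng.normal(0, 0.05, nf)), 1.0)

        frames_out.append(pd.DataFrame({
            "cell_id": c.cell_id,
            "colony_id": c.colony_id,
            "condition": condition.value,
            "frame": f,
            "time_h": t,
            "x": xy[:, 0],
            "y": xy[:, 1],
            "nuclear_area": area,
            "cherry": cherry,
            "venus": venus,
            "parent_id": c.parent_id,
        }))
    return pd.concat(frames_out, ignore_index=True)


# --------------------------------------------------------------------------
# public API


def simulate_lineage(params: SimulationParams, condition: Condition) -> TrackingTable:
    """Simulate all colonies of one condition into a per-frame tracking table.

    The generative truth is attached as ``table.truth`` (one row per cell,
    same schema as extracted records plus the true boundary frame).
    """
    condition = Condition(condition)
    tables, truths = [], []
    for ci in range(params.n_colonies):
        cells = _simulate_colony(params, condition, ci)
        tables.append(_render_colony(cells, params, condition, ci))
        truths.append(_truth_frame(cells, params, condition))
    df = pd.concat(tables, ignore_index=True)
    truth = pd.concat(truths, ignore_index=True)
    return TrackingTable(df=df, metadata=params.metadata, truth=truth)


def simulate_truth(params: SimulationParams, condition: Condition) -> pd.DataFrame:
    """Fast path: generative truth records only, no per-frame rendering."""
    condition = Condition(condition)
    truths = [
        _truth_frame(_simulate_colony(params, condition, ci), params, condition)
        for ci in range(params.n_colonies)
    ]
    return pd.concat(truths, ignore_index=True)


def simulate_dataset(params: SimulationParams) -> TrackingTable:
    """Simulate both conditions into a single table (truth concatenated)."""
    parts = [simulate_lineage(params, c) for c in (Condition.GROUND_STATE, Condition.DIFF)]
    df = pd.concat([p.df for p in parts], ignore_index=True)
    truth = pd.concat([p.truth for p in parts], ignore_index=True)
    return TrackingTable(df=df, metadata=params.metadata, truth=truth)


def ground_truth(table: TrackingTable) -> pd.DataFrame:
    """Return the generative truth attached to a simulated table."""
    if table.truth is None:
        raise ValueError("table was not produced by the simulator (no truth attached)")
    return table.truth


def apoptosis_overrides(truth: pd.DataFrame) -> pd.DataFrame:
    """Curation-override table flagging apoptotic cells (mimics manual annotation)."""
    apo = truth.loc[truth["fate"] == Fate.APOPTOSIS.value, ["cell_id"]].copy()
    apo["fate"] = Fate.APOPTOSIS.value
    return apo.reset_index(drop=True)
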