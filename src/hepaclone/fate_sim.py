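"""Stochastic 3D agent-based simulation of hepatoblast differentiation.

The model follows embryonic liver development in three phases: an initial
pool of hepatoblasts (P) expands by symmetric division (phase I); once the
pool reaches a threshold size, every subsequent hepatoblast division is a
differentiation event replacing the mother by a pair of daughters whose
fates are drawn from a fixed probability table over {H+C, C+C, H+H}
(phase II); differentiated hepatocytes (H) and biliary epithelial cells
(C, cholangiocytes/BECs) keep dividing at type-specific rates while
maintaining their fate (phase III).  Division times are exact Gillespie
draws: the waiting time to the next division is exponential with rate equal
to the sum of per-cell division rates and the dividing cell is chosen with
probability proportional to its own rate.

Rates are expressed per arbitrary time unit with 10 a.u. = 24 h, so the
default rate 1/10 corresponds to a 24-h cell cycle.  The simulation stops
at the first division that brings the total population to ``n_final``.

Two spatial modes are provided.  ``well-mixed`` tracks no positions (cell
fates never depend on position in this model, so this is the fast default).
``relaxed-3d`` places each daughter within ``placement_radius`` of its
mother and periodically relaxes overlaps with a soft-sphere repulsion plus
short-range adhesion.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FateModelParams",
    "SimulationResult",
    "EnsembleResult",
    "MODEL_PRESETS",
    "get_model_params",
    "load_fate_params",
    "sample_next_event",
    "divide_cell",
    "relax_positions",
    "run_simulation",
    "run_model",
    "ratio_trajectory",
]

# Cell-type codes used throughout the event log and count trajectories.
TYPE_P, TYPE_H, TYPE_C = 0, 1, 2
TYPE_NAMES = np.array(["P", "H", "C"])

WELL_MIXED = "well-mixed"
RELAXED_3D = "relaxed-3d"


@dataclass(frozen=True)
class FateModelParams:
    """Parameters of one fate model.

    ``p_hc``, ``p_cc``, ``p_hh`` are the probabilities that a
    differentiating hepatoblast division yields H+C, C+C or H+H daughters;
    they must sum to 1.  ``rate_p/c/h`` are per-cell division rates in
    1/a.u. (10 a.u. = 24 h).
    """

    p_hc: float
    p_cc: float
    p_hh: float
    rate_p: float = 0.1
    rate_c: float = 0.1
    rate_h: float = 0.1
    n_init: int = 100
    n_diff_threshold: int = 200
    n_final: int = 3000
    placement_radius: float = 1.0
    spatial_mode: str = WELL_MIXED
    name: str = "custom"

    def __post_init__(self) -> None:
        probs = (self.p_hc, self.p_cc, self.p_hh)
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError(f"fate probabilities must lie in [0, 1], got {probs}")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ValueError(f"fate probabilities must sum to 1, got {sum(probs)!r}")
        if min(self.rate_p, self.rate_c, self.rate_h) <= 0:
            raise ValueError("all division rates must be positive")
        if not (self.n_init <= self.n_diff_threshold < self.n_final):
            raise ValueError("require n_init <= n_diff_threshold < n_final")
        if self.placement_radius <= 0:
            raise ValueError("placement_radius must be positive")
        if self.spatial_mode not in (WELL_MIXED, RELAXED_3D):
            raise ValueError(f"unknown spatial_mode {self.spatial_mode!r}")

    @property
    def fate_probs(self) -> np.ndarray:
        return np.array([self.p_hc, self.p_cc, self.p_hh])

    def swapped(self) -> "FateModelParams":
        """Exchange the roles of H and C (p_cc<->p_hh, rate_c<->rate_h)."""
        return replace(
            self,
            p_cc=self.p_hh,
            p_hh=self.p_cc,
            rate_c=self.rate_h,
            rate_h=self.rate_c,
            name=f"{self.name}-swapped",
        )


#: The six fate parameterisations explored by the model: either all
#: hepatoblasts are bipotent (models 1-2), or the pool mixes bipotent and
#: unipotent hepatoblasts (models 3-6); BEC division is slowed to 1/15 in
#: models 2 and 5.
MODEL_PRESETS: dict[int, FateModelParams] = {
    1: FateModelParams(1.0, 0.0, 0.0, name="model1"),
    2: FateModelParams(1.0, 0.0, 0.0, rate_c=1 / 15, name="model2"),
    3: FateModelParams(0.5, 0.0, 0.5, name="model3"),
    4: FateModelParams(0.2, 0.05, 0.75, name="model4"),
    5: FateModelParams(0.2, 0.05, 0.75, rate_c=1 / 15, name="model5"),
    6: FateModelParams(0.2, 0.0, 0.8, name="model6"),
}


def get_model_params(model: int | str, **overrides) -> FateModelParams:
    """Return a preset (1-6) with optional field overrides."""
    preset = MODEL_PRESETS[int(model)]
    return replace(preset, **overrides) if overrides else preset


def load_fate_params(path: str | Path) -> FateModelParams:
    """Load parameters from a YAML/JSON config.

    The file either names a preset (``model: 4``) with optional overrides,
    or gives the full parameter set.
    """
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    model = cfg.pop("model", None)
    if model is not None and str(model) != "custom":
        return get_model_params(int(model), **cfg)
    return FateModelParams(**cfg)


@dataclass
class SimulationResult:
    """One replicate: final cells, event log, count trajectory."""

    params: FateModelParams
    seed: object
    cells: pd.DataFrame  # cell_id, cell_type, parent_id, birth_time [, x,y,z]
    events: pd.DataFrame  # time, parent_id, daughter_id, mother_type, fate_a, fate_b
    trajectory: pd.DataFrame  # time, n_p, n_h, n_c

    @property
    def final_counts(self) -> dict[str, int]:
        last = self.trajectory.iloc[-1]
        return {"P": int(last.n_p), "H": int(last.n_h), "C": int(last.n_c)}

    @property
    def final_ratio(self) -> float:
        """Final hepatocytes per BEC; NaN when no BECs exist (undefined)."""
        c = self.final_counts
        return c["H"] / c["C"] if c["C"] > 0 else float("nan")

    @property
    def ratio_defined(self) -> bool:
        return self.final_counts["C"] > 0


@dataclass
class EnsembleResult:
    """Independent replicates of one model plus the ratio summary."""

    params: FateModelParams
    replicates: list[SimulationResult]
    ratios: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.ratios = np.array([r.final_ratio for r in self.replicates])

    @property
    def mean_ratio(self) -> float:
        finite = self.ratios[np.isfinite(self.ratios)]
        return float(finite.mean()) if finite.size else float("nan")

    @property
    def sd_ratio(self) -> float:
        finite = self.ratios[np.isfinite(self.ratios)]
        return float(finite.std(ddof=1)) if finite.size > 1 else float("nan")

    @property
    def se_ratio(self) -> float:
        finite = self.ratios[np.isfinite(self.ratios)]
        if finite.size > 1:
            return float(finite.std(ddof=1) / np.sqrt(finite.size))
        return float("nan")

    def summary(self) -> dict:
        return {
            "model": self.params.name,
            "n_replicates": len(self.replicates),
            "mean_ratio_h_per_c": self.mean_ratio,
            "sd_ratio": self.sd_ratio,
            "se_ratio": self.se_ratio,
            "n_undefined": int(np.isnan(self.ratios).sum()),
            "replicate_ratios": [None if np.isnan(r) else float(r) for r in self.ratios],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2))


def sample_next_event(rates: np.ndarray, rng: np.random.Generator) -> tuple[float, int]:
    """Gillespie draw: (waiting time, index of the dividing cell).

    The waiting time is exponential with rate ``rates.sum()``; the dividing
    cell is chosen with probability proportional to its own rate.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.size == 0:
        raise ValueError("cannot sample an event from an empty population")
    if np.any(rates <= 0):
        raise ValueError("all per-cell rates must be positive")
    total = rates.sum()
    waiting_time = rng.exponential(1.0 / total)
    # inverse-CDF draw on the cumulative rate vector
    idx = int(np.searchsorted(np.cumsum(rates), rng.uniform(0, total), side="right"))
    return waiting_time, min(idx, rates.size - 1)


class _SimState:
    """Mutable simulation state with O(1) per-event bookkeeping."""

    def __init__(self, params: FateModelParams, rng: np.random.Generator):
        self.params = params
        self.rng = rng
        self.time = 0.0
        n = params.n_init
        self.types = [TYPE_P] * n
        self.parents: list[int] = [-1] * n
        self.birth_times = [0.0] * n
        # index lists per type; removal is swap-pop so membership is O(1)
        self.buckets: list[list[int]] = [list(range(n)), [], []]
        self.slot_of = list(range(n))  # position of cell i inside its bucket
        self.diff_active = n >= params.n_diff_threshold
        if params.spatial_mode == RELAXED_3D:
            r0 = params.placement_radius * max(1.0, n ** (1 / 3))
            self.positions = list(_uniform_ball(rng, n, r0))
        else:
            self.positions = None

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.buckets[0]), len(self.buckets[1]), len(self.buckets[2]))

    @property
    def n_cells(self) -> int:
        return len(self.types)

    def type_rates(self) -> np.ndarray:
        p = self.params
        np_, nh, nc = self.counts
        return np.array([np_ * p.rate_p, nh * p.rate_h, nc * p.rate_c])

    def _retype(self, cell: int, new_type: int) -> None:
        old = self.types[cell]
        if old == new_type:
            return
        bucket = self.buckets[old]
        slot = self.slot_of[cell]
        last = bucket[-1]
        bucket[slot] = last
        self.slot_of[last] = slot
        bucket.pop()
        self.types[cell] = new_type
        self.slot_of[cell] = len(self.buckets[new_type])
        self.buckets[new_type].append(cell)

    def _add_cell(self, cell_type: int, parent: int, position=None) -> int:
        cid = len(self.types)
        self.types.append(cell_type)
        self.parents.append(parent)
        self.birth_times.append(self.time)
        self.slot_of.append(len(self.buckets[cell_type]))
        self.buckets[cell_type].append(cid)
        if self.positions is not None:
            self.positions.append(position)
        return cid


def _uniform_ball(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    """n points uniform in a ball of the given radius."""
    direction = rng.normal(size=(n, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    r = radius * rng.uniform(size=(n, 1)) ** (1 / 3)
    return direction * r


def divide_cell(state: _SimState, cell_id: int, rng: np.random.Generator) -> tuple[int, int, int]:
    """Execute one division of ``cell_id``; return (fate_a, fate_b, daughter_id).

    Fate_a is the fate taken by the mother's record (the mother is replaced
    by daughter A in place), fate_b the fate of the appended daughter B.  A
    hepatoblast dividing while differentiation is active draws the daughter
    pair from the fate table; any other division is symmetric.
    """
    if cell_id < 0 or cell_id >= state.n_cells:
        raise ValueError(f"cell {cell_id} does not exist")
    params = state.params
    mother_type = state.types[cell_id]
    if mother_type == TYPE_P and state.diff_active:
        pair = rng.choice(3, p=params.fate_probs)
        fate_a, fate_b = [(TYPE_H, TYPE_C), (TYPE_C, TYPE_C), (TYPE_H, TYPE_H)][pair]
    else:
        fate_a = fate_b = mother_type
    position = None
    if state.positions is not None:
        offset = _uniform_ball(rng, 1, params.placement_radius)[0]
        position = state.positions[cell_id] + offset
    state._retype(cell_id, fate_a)
    daughter = state._add_cell(fate_b, cell_id, position)
    return fate_a, fate_b, daughter


def relax_positions(
    positions: np.ndarray,
    min_separation: float = 1.0,
    adhesion: float = 0.05,
    cutoff: float | None = None,
    max_iter: int = 200,
    tol: float = 1e-3,
    rng: np.random.Generator | None = None,
    warn: bool = True,
) -> tuple[np.ndarray, bool]:
    """Relax a point cloud with soft-sphere repulsion and short-range adhesion.

    Overlapping pairs (distance < ``min_separation``) are pushed apart along
    the pair axis; pairs between ``min_separation`` and ``cutoff`` (default
    1.5x) feel a weak attraction that keeps the aggregate cohesive.  The
    attraction acts during the first half of the iteration budget only, so
    the final packing satisfies the hard-core constraint: iteration stops
    once no pair is closer than ``min_separation - tol``, or at
    ``max_iter`` with a warning and the best-effort configuration.
    """
    from scipy.spatial import cKDTree

    if rng is None:
        rng = np.random.default_rng(0)
    pos = np.array(positions, dtype=float)
    if pos.ndim != 2:
        raise ValueError("positions must be an (n, 3) array")
    if cutoff is None:
        cutoff = 1.5 * min_separation
    n = len(pos)
    if n < 2:
        return pos, True
    for it in range(max_iter):
        k_adh = adhesion if it < max_iter // 2 else 0.0
        tree = cKDTree(pos)
        pairs = np.array(sorted(tree.query_pairs(cutoff)))
        if pairs.size == 0:
            return pos, True
        i, j = pairs[:, 0], pairs[:, 1]
        delta = pos[j] - pos[i]
        dist = np.linalg.norm(delta, axis=1)
        degenerate = dist < 1e-12
        if degenerate.any():
            delta[degenerate] = _uniform_ball(rng, int(degenerate.sum()), 1.0)
            delta[degenerate] /= np.linalg.norm(delta[degenerate], axis=1, keepdims=True)
            dist[degenerate] = 1e-12
        unit = delta / dist[:, None]
        overlap = np.clip(min_separation - dist, 0.0, None)
        attract = k_adh * np.clip(dist - min_separation, 0.0, None)
        # half-step displacement per member of the pair
        step = 0.5 * (overlap - attract)
        disp = np.zeros_like(pos)
        np.add.at(disp, i, -step[:, None] * unit)
        np.add.at(disp, j, step[:, None] * unit)
        pos += disp
        if overlap.max() <= tol:
            return pos, True
    if warn:
        warnings.warn(
            f"position relaxation did not converge in {max_iter} iterations "
            f"(residual overlap {overlap.max():.3g})",
            RuntimeWarning,
        )
    return pos, False


def run_simulation(
    params: FateModelParams,
    seed: int | np.random.SeedSequence | None = None,
    relax_interval: int = 25,
) -> SimulationResult:
    """Run one replicate until the population reaches ``n_final`` cells."""
    rng = np.random.default_rng(seed)
    state = _SimState(params, rng)
    events: list[tuple] = []
    traj: list[tuple] = [(0.0, *state.counts)]
    spatial = params.spatial_mode == RELAXED_3D
    since_relax = 0
    while state.n_cells < params.n_final:
        type_rates = state.type_rates()
        # O(1) two-stage draw: type proportional to (count x rate), then a
        # uniformly chosen cell of that type -- identical in law to the
        # per-cell Gillespie draw, since cells of a type share one rate.
        live_types = np.flatnonzero(type_rates > 0)
        waiting_time, which = sample_next_event(type_rates[live_types], rng)
        which_type = int(live_types[which])
        state.time += waiting_time
        bucket = state.buckets[which_type]
        cell = bucket[int(rng.integers(len(bucket)))]
        mother_type = state.types[cell]
        fate_a, fate_b, daughter = divide_cell(state, cell, rng)
        events.append((state.time, cell, daughter, mother_type, fate_a, fate_b))
        traj.append((state.time, *state.counts))
        if not state.diff_active and len(state.buckets[TYPE_P]) >= params.n_diff_threshold:
            state.diff_active = True
        if spatial:
            since_relax += 1
            if since_relax >= relax_interval:
                # interim relaxations run a short budget; residual overlap
                # is expected and resolved by the final full relaxation
                pos, _ = relax_positions(
                    np.asarray(state.positions), max_iter=20, rng=rng, warn=False
                )
                state.positions = list(pos)
                since_relax = 0
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(state.n_cells),
            "cell_type": TYPE_NAMES[np.array(state.types)],
            "parent_id": np.array(state.parents),
            "birth_time": np.array(state.birth_times),
        }
    )
    if spatial:
        # final packing: 1% residual overlap is acceptable at cell scale
        pos, _ = relax_positions(np.asarray(state.positions), max_iter=400, tol=0.01, rng=rng)
        cells[["x", "y", "z"]] = pos
    event_df = pd.DataFrame(
        events, columns=["time", "parent_id", "daughter_id", "mother_type", "fate_a", "fate_b"]
    )
    for col in ("mother_type", "fate_a", "fate_b"):
        event_df[col] = TYPE_NAMES[event_df[col].to_numpy(dtype=int)]
    traj_df = pd.DataFrame(traj, columns=["time", "n_p", "n_h", "n_c"])
    return SimulationResult(params=params, seed=seed, cells=cells, events=event_df, trajectory=traj_df)


def run_model(
    params: FateModelParams | int,
    n_reps: int = 10,
    seed: int | None = None,
) -> EnsembleResult:
    """Run ``n_reps`` independent replicates from per-replicate substreams."""
    if isinstance(params, int):
        params = get_model_params(params)
    streams = np.random.SeedSequence(seed).spawn(n_reps)
    replicates = [run_simulation(params, seed=s) for s in streams]
    return EnsembleResult(params=params, replicates=replicates)


def ratio_trajectory(result: SimulationResult) -> pd.DataFrame:
    """Cell-type fractions over simulation time plus the final H:C ratio.

    Returns a frame with columns time, frac_p, frac_h, frac_c; the final
    hepatocytes-per-BEC ratio is attached as ``df.attrs["final_ratio"]``
    (NaN when undefined, i.e. no BECs at termination).
    """
    t = result.trajectory
    total = (t.n_p + t.n_h + t.n_c).to_numpy(dtype=float)
    df = pd.DataFrame(
        {
            "time": t.time,
            "frac_p": t.n_p / total,
            "frac_h": t.n_h / total,
            "frac_c": t.n_c / total,
        }
    )
    df.attrs["final_ratio"] = result.final_ratio
    df.attrs["ratio_defined"] = result.ratio_defined
    return df
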