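"""Synthetic multispectral 3D labelled-liver cohorts with ground truth.

Emulates the data produced by heat-shock-induced multicolour lineage
labelling of hepatoblasts followed by whole-mount imaging and nuclear
segmentation: per liver, a table of labelled nuclei with 3D coordinates
(μm), one of four colours, and a hepatocyte/BEC fate.  The generative
model mirrors what the downstream analysis assumes:

* induction — the number of labelled founder progenitors per liver is
  highly heterogeneous; a two-component mixture (sparse majority plus a
  densely induced minority) is calibrated so that about half the livers
  carry fewer than 30 labelled cells while about 10% carry more than 100;
* colours — founders draw one of four fluorophores independently with
  configurable frequencies (default 1/4 each);
* clone growth — each founder grows by a pure-birth (Yule) process over a
  unit observation window with division rate ln<k>, so realised clone
  sizes are geometric with mean <k> (exponential tail, the discrete
  analogue of the clone-size scaling law) and the number of divisions
  along the founder's own lineage is exactly Poisson(ln<k>);
* fates — each clone is pure-hepatocyte, mixed, or pure-BEC with the
  observed class frequencies (default 88.8 / 10.7 / 0.5%); mixed clones
  have at least two cells and a uniformly drawn BEC share;
* space — founders sit uniformly inside the pre-expansion organ
  ellipsoid, every daughter lands within the dispersal radius of its
  mother, a jitter term emulates residual nuclear movement, and all
  positions are scaled by the linear organ-expansion factor (default
  3.2-fold volume growth, i.e. 3.2^(1/3) linear).

Everything is reproducible from a master seed.  The emitted cell table
uses the same CSV dialect consumed by clone reconstruction; the ground
truth records per-cell clone membership and per-clone size, fate
composition and division counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .clone_call import DEFAULT_COLOURS, FATE_BEC, FATE_HEPATOCYTE
from .spatial_stats import EllipsoidSurface

__all__ = [
    "SyntheticCohortParams",
    "GroundTruth",
    "sample_clone_sizes",
    "generate_liver",
    "generate_cohort",
]

CLONE_TYPES = ("pure-hepatocyte", "mixed", "pure-BEC")


@dataclass(frozen=True)
class SyntheticCohortParams:
    """Generator settings; the defaults define the reference conditions."""

    n_livers: int = 97
    semi_axes_um: tuple[float, float, float] = (110.0, 80.0, 60.0)
    expansion_factor: float = 3.2 ** (1 / 3)
    colours: tuple[str, ...] = DEFAULT_COLOURS
    colour_freqs: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    mean_clone_size: float = 4.5
    dispersal_radius_um: float = 10.0
    position_jitter_um: float = 5.0
    fate_type_probs: tuple[float, float, float] = (0.888, 0.107, 0.005)
    induction_p_high: float = 0.11
    induction_mu_low: float = 4.0
    induction_mu_high: float = 30.0
    n_founders: int | None = None  # fixed founder count, bypassing induction
    min_founder_separation_um: float | None = None

    def __post_init__(self) -> None:
        if self.n_livers < 1:
            raise ValueError("n_livers must be >= 1")
        if len(self.colour_freqs) != len(self.colours):
            raise ValueError("one frequency per colour required")
        if abs(sum(self.colour_freqs) - 1.0) > 1e-9 or min(self.colour_freqs) < 0:
            raise ValueError("colour frequencies must be non-negative and sum to 1")
        if abs(sum(self.fate_type_probs) - 1.0) > 1e-9 or min(self.fate_type_probs) < 0:
            raise ValueError("fate-type probabilities must be non-negative and sum to 1")
        if self.mean_clone_size <= 1.0:
            raise ValueError("mean_clone_size must exceed 1")
        for name in ("dispersal_radius_um", "position_jitter_um", "expansion_factor",
                     "induction_p_high", "induction_mu_low", "induction_mu_high"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if min(self.semi_axes_um) <= 0:
            raise ValueError("semi_axes_um must be positive")

    @property
    def division_rate(self) -> float:
        """Yule rate over the unit window giving mean size <k>: a = ln<k>."""
        return math.log(self.mean_clone_size)

    def surface(self) -> EllipsoidSurface:
        """The (post-expansion) organ surface all cells lie within."""
        return EllipsoidSurface(self.semi_axes_um)


@dataclass
class GroundTruth:
    """Per-cell clone membership plus per-clone truth."""

    cell_clones: pd.DataFrame  # liver_id, cell_id, true_clone_id
    clones: pd.DataFrame  # per-clone size, fate composition, divisions, founder xyz


def _grow_clone(
    rng: np.random.Generator, rate: float, t_window: float = 1.0, min_size: int = 1
) -> tuple[int, int, list[int]]:
    """Simulate one Yule clone; return (size, lineage divisions, parents).

    Every live cell divides at ``rate``; sizes at the end of the window
    are geometric with mean exp(rate * t_window).  The founder occupies
    index 0 and its own divisions over the window form a renewal process
    with exponential gaps, hence a Poisson(rate * t_window) count.
    ``parents[i]`` is the mother index of cell i (founder: -1).
    """
    while True:
        t = 0.0
        parents = [-1]
        lineage_divisions = 0
        n = 1
        while True:
            t += rng.exponential(1.0 / (rate * n))
            if t > t_window:
                break
            mother = int(rng.integers(n))
            if mother == 0:
                lineage_divisions += 1
            parents.append(mother)
            n += 1
        if n >= min_size:
            return n, lineage_divisions, parents


def sample_clone_sizes(
    n_clones: int, mean_size: float = 4.5, seed: int | None = None
) -> pd.DataFrame:
    """Sizes and division counts of ``n_clones`` independent Yule clones.

    Columns: ``size``, ``n_divisions_total`` (= size - 1) and
    ``n_divisions_lineage`` (founder-lineage divisions, Poisson by
    construction).
    """
    rng = np.random.default_rng(seed)
    rate = math.log(mean_size)
    rows = [_grow_clone(rng, rate)[:2] for _ in range(n_clones)]
    df = pd.DataFrame(rows, columns=["size", "n_divisions_lineage"])
    df["n_divisions_total"] = df["size"] - 1
    return df[["size", "n_divisions_total", "n_divisions_lineage"]]


def _uniform_in_ellipsoid(rng: np.random.Generator, n: int, semi_axes) -> np.ndarray:
    direction = rng.normal(size=(n, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    r = rng.uniform(size=(n, 1)) ** (1 / 3)
    return direction * r * np.asarray(semi_axes)


def _uniform_ball(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    direction = rng.normal(size=(n, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    return direction * radius * rng.uniform(size=(n, 1)) ** (1 / 3)


def _place_founders(
    rng: np.random.Generator, n: int, semi_axes, min_separation: float | None
) -> np.ndarray:
    if min_separation is None:
        return _uniform_in_ellipsoid(rng, n, semi_axes)
    placed: list[np.ndarray] = []
    for _ in range(n):
        for _attempt in range(2000):
            cand = _uniform_in_ellipsoid(rng, 1, semi_axes)[0]
            if all(np.linalg.norm(cand - q) >= min_separation for q in placed):
                placed.append(cand)
                break
        else:
            raise ValueError(
                f"organ geometry too small to place {n} founders at "
                f"min separation {min_separation} μm"
            )
    return np.array(placed)


def _draw_n_founders(rng: np.random.Generator, params: SyntheticCohortParams) -> int:
    if params.n_founders is not None:
        return params.n_founders
    mu = (
        params.induction_mu_high
        if rng.uniform() < params.induction_p_high
        else params.induction_mu_low
    )
    return 1 + int(rng.poisson(mu))


def generate_liver(
    params: SyntheticCohortParams,
    seed: int | np.random.SeedSequence | None = None,
    liver_id: str = "L001",
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one labelled liver and its ground truth."""
    rng = np.random.default_rng(seed)
    n_founders = _draw_n_founders(rng, params)
    pre_axes = np.asarray(params.semi_axes_um) / params.expansion_factor
    founders = _place_founders(rng, n_founders, pre_axes, params.min_founder_separation_um)
    colour_idx = rng.choice(len(params.colours), size=n_founders, p=params.colour_freqs)
    clone_types = rng.choice(3, size=n_founders, p=params.fate_type_probs)

    cell_rows, truth_cells, truth_clones = [], [], []
    cell_id = 0
    for clone_id in range(n_founders):
        ctype = CLONE_TYPES[clone_types[clone_id]]
        size, lineage_div, parents = _grow_clone(
            rng, params.division_rate, min_size=2 if ctype == "mixed" else 1
        )
        pos = np.empty((size, 3))
        pos[0] = founders[clone_id]
        for i in range(1, size):
            pos[i] = pos[parents[i]] + _uniform_ball(rng, 1, params.dispersal_radius_um)[0]
        if params.position_jitter_um > 0:
            pos += _uniform_ball(rng, size, params.position_jitter_um)
        pos *= params.expansion_factor
        # keep every nucleus inside the expanded organ surface
        radial = np.sqrt(((pos / params.semi_axes_um) ** 2).sum(axis=1))
        outside = radial > 1.0
        pos[outside] *= (0.999 / radial[outside])[:, None]

        fates = np.full(size, FATE_HEPATOCYTE, dtype=object)
        n_bec = 0
        if ctype == "pure-BEC":
            fates[:] = FATE_BEC
            n_bec = size
        elif ctype == "mixed":
            n_bec = int(rng.integers(1, size))  # uniform over feasible splits
            fates[rng.choice(size, size=n_bec, replace=False)] = FATE_BEC

        colour = params.colours[colour_idx[clone_id]]
        for i in range(size):
            cell_rows.append(
                (liver_id, cell_id, pos[i, 0], pos[i, 1], pos[i, 2], colour, fates[i])
            )
            truth_cells.append((liver_id, cell_id, clone_id))
            cell_id += 1
        truth_clones.append(
            {
                "liver_id": liver_id,
                "true_clone_id": clone_id,
                "colour": colour,
                "size": size,
                "n_bec": n_bec,
                "clone_type": ctype,
                "n_divisions_total": size - 1,
                "n_divisions_lineage": lineage_div,
                "founder_x_um": founders[clone_id, 0] * params.expansion_factor,
                "founder_y_um": founders[clone_id, 1] * params.expansion_factor,
                "founder_z_um": founders[clone_id, 2] * params.expansion_factor,
            }
        )
    cells = pd.DataFrame(
        cell_rows, columns=["liver_id", "cell_id", "x_um", "y_um", "z_um", "colour", "fate"]
    )
    truth = GroundTruth(
        cell_clones=pd.DataFrame(truth_cells, columns=["liver_id", "cell_id", "true_clone_id"]),
        clones=pd.DataFrame(truth_clones),
    )
    return cells, truth


def generate_cohort(
    params: SyntheticCohortParams | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a cohort of livers; reproducible from the master seed."""
    if params is None:
        params = SyntheticCohortParams()
    streams = np.random.SeedSequence(seed).spawn(params.n_livers)
    width = max(3, len(str(params.n_livers)))
    cells_parts, cell_truth_parts, clone_truth_parts = [], [], []
    for i, stream in enumerate(streams):
        liver_id = f"L{i + 1:0{width}d}"
        cells, truth = generate_liver(params, seed=stream, liver_id=liver_id)
        cells_parts.append(cells)
        cell_truth_parts.append(truth.cell_clones)
        clone_truth_parts.append(truth.clones)
    return (
        pd.concat(cells_parts, ignore_index=True),
        GroundTruth(
            cell_clones=pd.concat(cell_truth_parts, ignore_index=True),
            clones=pd.concat(clone_truth_parts, ignore_index=True),
        ),
    )
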