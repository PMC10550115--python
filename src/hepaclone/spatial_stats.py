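"""Tissue-level spatial statistics for segmented-nucleus point clouds.

Covers the descriptive analyses applied to whole-organ datasets: cell-type
ratios/proportions, distances of nuclei to the organ surface (e.g. are
proliferating cells enriched at the periphery?), and nearest-neighbour
distance distributions (e.g. are proliferating cells clustered or
dispersed?).  Organ geometry is either an analytic ellipsoid (the default
for synthetic livers; point-to-surface distance solved by root finding on
the projection equation) or a triangulated mesh (brute-force
point-to-triangle minimisation).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.spatial import cKDTree

__all__ = [
    "EllipsoidSurface",
    "MeshSurface",
    "RatioSummary",
    "SurfaceDistanceResult",
    "cell_type_ratio",
    "distance_to_surface",
    "nearest_neighbour_distances",
]


@dataclass(frozen=True)
class EllipsoidSurface:
    """Axis-aligned ellipsoid (x/a)^2 + (y/b)^2 + (z/c)^2 = 1, in μm."""

    semi_axes: tuple[float, float, float]
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.semi_axes) != 3 or min(self.semi_axes) <= 0:
            raise ValueError("semi_axes must be three positive lengths")

    @classmethod
    def from_json(cls, path: str | Path) -> "EllipsoidSurface":
        cfg = json.loads(Path(path).read_text())
        return cls(tuple(cfg["semi_axes"]), tuple(cfg.get("center", (0, 0, 0))))

    def contains(self, points: np.ndarray, tol: float = 0.0) -> np.ndarray:
        p = (np.atleast_2d(points) - self.center) / self.semi_axes
        return (p**2).sum(axis=1) <= 1.0 + tol

    def _distance_one(self, p: np.ndarray) -> float:
        """Unsigned distance of one point to the surface.

        The nearest surface point y solves y_i = a_i^2 p_i / (t + a_i^2)
        with y on the ellipsoid; the Lagrange parameter t is the unique
        root of a strictly decreasing function on (-a_min^2, inf).  Points
        on a symmetry axis where the root disappears are handled by the
        degenerate closed form.
        """
        a = np.asarray(self.semi_axes, dtype=float)
        if np.allclose(p, 0.0):
            return float(a.min())
        a2 = a**2
        a2min = a2.min()

        def f(t):
            return ((a * p / (t + a2)) ** 2).sum() - 1.0

        t_lo = -a2min * (1 - 1e-12) + 1e-12
        t_hi = float(np.sqrt(((a * p) ** 2).sum())) + 1.0
        if f(t_lo) < 0.0:
            # degenerate: p has no component along the shortest axis; the
            # nearest point gains a free component on that axis
            mask = a2 > a2min + 1e-12
            y = np.zeros(3)
            y[mask] = a2[mask] * p[mask] / (a2[mask] - a2min)
            s = ((y[mask] / a[mask]) ** 2).sum()
            if s < 1.0:
                off_axis = float(np.sqrt(a2min * (1.0 - s)))
                return float(np.sqrt(((p[mask] - y[mask]) ** 2).sum() + off_axis**2))
            # constrained to the equatorial section: fall through with a
            # slightly perturbed bracket
            t_lo = -a2min * (1 - 1e-9)
        t = brentq(f, t_lo, t_hi, xtol=1e-10)
        y = a2 * p / (t + a2)
        return float(np.linalg.norm(p - y))

    def distance(self, points: np.ndarray) -> np.ndarray:
        """Unsigned distances to the nearest surface point (μm)."""
        pts = np.atleast_2d(points).astype(float) - self.center
        return np.array([self._distance_one(p) for p in pts])


@dataclass(frozen=True)
class MeshSurface:
    """Closed triangulated surface given by vertices (n,3) and faces (m,3)."""

    vertices: np.ndarray
    faces: np.ndarray

    def distance(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points).astype(float)
        tri = np.asarray(self.vertices, dtype=float)[np.asarray(self.faces)]
        return np.array([_point_triangles_distance(p, tri).min() for p in pts])

    def contains(self, points: np.ndarray, tol: float = 0.0) -> np.ndarray:
        # inside/outside for a general mesh is not resolved here
        return np.ones(len(np.atleast_2d(points)), dtype=bool)


def _point_triangles_distance(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Distance from point p to each triangle in tri (m,3,3), vectorised."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = (ab * ap).sum(1)
    d2 = (ac * ap).sum(1)
    bp = p - b
    d3 = (ab * bp).sum(1)
    d4 = (ac * bp).sum(1)
    cp = p - c
    d5 = (ab * cp).sum(1)
    d6 = (ac * cp).sum(1)
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    v = np.where(np.abs(denom) > 1e-300, vb / np.where(denom == 0, 1, denom), 0.0)
    w = np.where(np.abs(denom) > 1e-300, vc / np.where(denom == 0, 1, denom), 0.0)
    closest = a + v[:, None] * ab + w[:, None] * ac  # face-interior candidate
    # clamp to the appropriate vertex/edge region (Ericson, Real-Time
    # Collision Detection, ch. 5.1.5)
    closest = np.where((d1 <= 0)[:, None] & (d2 <= 0)[:, None], a, closest)
    closest = np.where((d3 >= 0)[:, None] & (d4 <= d3)[:, None], b, closest)
    closest = np.where((d6 >= 0)[:, None] & (d5 <= d6)[:, None], c, closest)
    t_ab = np.clip(d1 / np.where(d1 - d3 == 0, 1, d1 - d3), 0, 1)
    on_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    closest = np.where(on_ab[:, None], a + t_ab[:, None] * ab, closest)
    t_ac = np.clip(d2 / np.where(d2 - d6 == 0, 1, d2 - d6), 0, 1)
    on_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    closest = np.where(on_ac[:, None], a + t_ac[:, None] * ac, closest)
    bc = c - b
    t_bc = np.clip((d4 - d3) / np.where((d4 - d3) + (d5 - d6) == 0, 1, (d4 - d3) + (d5 - d6)), 0, 1)
    on_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    closest = np.where(on_bc[:, None], b + t_bc[:, None] * bc, closest)
    return np.linalg.norm(p - closest, axis=1)


@dataclass
class RatioSummary:
    """Counts, proportions and the 1:x BEC-to-hepatocyte ratio."""

    counts: dict[str, int]
    proportions: dict[str, float] = field(init=False)
    hepatocytes_per_bec: float = field(init=False)

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        if total <= 0:
            raise ValueError("at least one cell-type count must be positive")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be non-negative")
        self.proportions = {k: v / total for k, v in self.counts.items()}
        n_bec = self.counts.get("bec", 0)
        n_hep = self.counts.get("hepatocyte", 0)
        self.hepatocytes_per_bec = n_hep / n_bec if n_bec > 0 else float("nan")

    @property
    def ratio_defined(self) -> bool:
        return np.isfinite(self.hepatocytes_per_bec)

    def as_one_to_x(self) -> str:
        if not self.ratio_defined:
            return "undefined (no BECs)"
        return f"1:{self.hepatocytes_per_bec:.1f}"


def cell_type_ratio(counts: dict[str, int]) -> RatioSummary:
    """Proportions per cell type and the hepatocytes-per-BEC ratio."""
    return RatioSummary(counts=dict(counts))


@dataclass
class SurfaceDistanceResult:
    """Per-cell surface distances and the marked-vs-rest comparison."""

    distances: np.ndarray
    marked: np.ndarray | None = None
    statistic: float = float("nan")
    pvalue: float = float("nan")
    effect_size: float = float("nan")  # Cohen's d, marked minus rest
    test: str = "t"

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"distance_to_surface_um": self.distances})
        if self.marked is not None:
            df["marked"] = self.marked
        return df


def distance_to_surface(
    cells: pd.DataFrame,
    surface,
    marker: str | None = None,
    test: str = "t",
    tol: float = 1e-6,
) -> SurfaceDistanceResult:
    """Distances of nuclei to the organ surface, with group comparison.

    ``marker`` names a boolean column (e.g. EdU status); the marked subset
    is compared with the remaining cells by a two-tailed two-sample t test
    (``test="t"``) or a Mann-Whitney rank-sum test (``test="ranksum"``,
    often preferable for skewed distance distributions), with Cohen's d as
    effect size.  Cells outside the surface beyond ``tol`` trigger a
    warning but are retained with their unsigned distance.
    """
    xyz = cells[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    inside = surface.contains(xyz, tol=tol)
    if not inside.all():
        warnings.warn(
            f"{(~inside).sum()} cell(s) lie outside the organ surface; "
            "distances reported unsigned",
            RuntimeWarning,
        )
    dist = surface.distance(xyz)
    if marker is None:
        return SurfaceDistanceResult(distances=dist)
    marked = cells[marker].to_numpy(dtype=bool)
    if marked.all() or not marked.any():
        raise ValueError("marker column must split the cells into two groups")
    d_m, d_o = dist[marked], dist[~marked]
    if test == "t":
        stat, p = stats.ttest_ind(d_m, d_o, equal_var=False)
    elif test == "ranksum":
        stat, p = stats.mannwhitneyu(d_m, d_o, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    pooled_sd = np.sqrt((d_m.var(ddof=1) + d_o.var(ddof=1)) / 2)
    d_eff = (d_m.mean() - d_o.mean()) / pooled_sd if pooled_sd > 0 else float("nan")
    return SurfaceDistanceResult(
        distances=dist,
        marked=marked,
        statistic=float(stat),
        pvalue=float(p),
        effect_size=float(d_eff),
        test=test,
    )


def nearest_neighbour_distances(
    query: np.ndarray,
    reference: np.ndarray,
    exclude_self: bool | None = None,
) -> pd.DataFrame:
    """Distance of each query cell to its nearest reference cell.

    ``exclude_self`` defaults to auto-detection (the same array passed
    twice, or identical contents).  Returns a frame of distances; summary
    quantiles sit in ``df.attrs["quantiles"]``.
    """
    query = np.atleast_2d(np.asarray(query, dtype=float))
    reference = np.atleast_2d(np.asarray(reference, dtype=float))
    if reference.size == 0:
        raise ValueError("reference set must be non-empty")
    if exclude_self is None:
        exclude_self = query is reference or (
            query.shape == reference.shape and np.array_equal(query, reference)
        )
    if exclude_self and len(reference) < 2:
        raise ValueError("self-matches excluded but the reference has no other cell")
    tree = cKDTree(reference)
    if exclude_self:
        d, _ = tree.query(query, k=2)
        nn = d[:, 1]
    else:
        nn, _ = tree.query(query, k=1)
    df = pd.DataFrame({"nn_distance_um": nn})
    df.attrs["quantiles"] = {
        q: float(np.quantile(nn, q)) for q in (0.05, 0.25, 0.5, 0.75, 0.95)
    }
    return df
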