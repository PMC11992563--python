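"""Spatial-order statistics for point patterns: NND, g(r), Ripley's K/L, Voronoi.

These statistics contrast random (CSR), lattice-like and clustered
organization. Under complete spatial randomness with intensity lambda the
mean nearest-neighbor distance is 1/(2 sqrt(lambda)), the pair correlation
g(r) -> 1, Ripley's K(r) -> pi r^2 (so L(r) - r -> 0), and Poisson-Voronoi
cell areas have a coefficient of variation of about 0.53.

Edge handling: ``toroidal`` uses the periodic metric (exact, no bias);
``guard`` keeps only points at least r_max from the border as centers while
all points remain available as neighbors; ``none`` applies no correction
(biased near the border, provided for completeness).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.spatial import QhullError, Voronoi, cKDTree

from .errors import ParameterError, UndefinedStatisticError
from .geometry import FieldGeometry

ESTIMATORS = ("nnd_hist", "pair_corr", "ripley_k", "ripley_l_minus_r", "voronoi")


@dataclass
class SpatialCurve:
    """A binned spatial statistic: radii (nm) against values."""

    radii: np.ndarray
    values: np.ndarray
    estimator: str
    edge_mode: str

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.radii) <= 0):
            raise ParameterError("radii must be strictly increasing")


def _as_points(points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    return points


def _tree(points: np.ndarray, geometry: FieldGeometry) -> cKDTree:
    if geometry.is_toroidal:
        box = (geometry.width, geometry.height)
        return cKDTree(np.mod(points, box), boxsize=box)
    return cKDTree(points)


def nearest_neighbor_distances(points: np.ndarray, geometry: FieldGeometry) -> np.ndarray:
    """Distance from each point to its nearest other point (nm)."""
    points = _as_points(points)
    if len(points) < 2:
        raise UndefinedStatisticError("nearest-neighbor distances need at least 2 points")
    tree = _tree(points, geometry)
    d, _ = tree.query(tree.data, k=2)
    return d[:, 1]


def _guard_centers(points: np.ndarray, geometry: FieldGeometry, r_max: float) -> np.ndarray:
    inside = (
        (points[:, 0] >= r_max)
        & (points[:, 0] <= geometry.width - r_max)
        & (points[:, 1] >= r_max)
        & (points[:, 1] <= geometry.height - r_max)
    )
    return np.flatnonzero(inside)


def _pair_counts(
    points: np.ndarray, geometry: FieldGeometry, edges: np.ndarray, edge_mode: str
) -> Tuple[np.ndarray, int]:
    """Ordered center->neighbor pair counts per distance bin, and the center count."""
    all_tree = _tree(points, geometry)
    if edge_mode == "toroidal":
        if not geometry.is_toroidal:
            raise ParameterError("toroidal edge mode requires a toroidal geometry")
        centers_idx = np.arange(len(points))
        center_tree = all_tree
    elif edge_mode == "guard":
        centers_idx = _guard_centers(points, geometry, edges[-1])
        if len(centers_idx) == 0:
            raise ParameterError("guard region is empty; reduce r_max")
        center_tree = cKDTree(points[centers_idx])
    elif edge_mode == "none":
        centers_idx = np.arange(len(points))
        center_tree = all_tree
    else:
        raise ParameterError(f"unknown edge mode {edge_mode!r}")
    cum = center_tree.count_neighbors(all_tree, edges).astype(float)
    cum -= len(centers_idx)  # self pairs sit at distance 0, present in every cumulative count
    counts = np.diff(cum)
    counts[0] += cum[0]  # coincident distinct points (distance exactly 0) belong in the first bin
    return counts, len(centers_idx)


def pair_autocorrelation(
    points: np.ndarray,
    geometry: FieldGeometry,
    bin_width: float,
    r_max: float,
    edge_mode: str = "toroidal",
) -> SpatialCurve:
    """Pair correlation function g(r), normalized so that CSR -> 1.

    g(r_k) = (ordered pair count in bin k) / (n_centers * lambda * annulus_k),
    with lambda the global intensity n/area.
    """
    points = _as_points(points)
    if len(points) < 2:
        raise UndefinedStatisticError("pair correlation needs at least 2 points")
    if bin_width <= 0:
        raise ParameterError("bin_width must be positive")
    if geometry.is_toroidal and r_max > min(geometry.width, geometry.height) / 2:
        raise ParameterError("r_max exceeds half the field size (toroidal distances fold back)")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    pair_counts, n_centers = _pair_counts(points, geometry, edges, edge_mode)
    lam = len(points) / geometry.area_nm2
    annuli = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    values = pair_counts / (n_centers * lam * annuli)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return SpatialCurve(centers, values, "pair_corr", edge_mode)


def ripley_k(
    points: np.ndarray,
    geometry: FieldGeometry,
    radii: np.ndarray,
    edge_mode: str = "toroidal",
) -> Tuple[SpatialCurve, SpatialCurve]:
    """Ripley's K(r) and the variance-stabilized L(r) - r.

    K(r) = (1/(n_centers * lambda)) * sum_i #{j != i : d_ij <= r};
    L(r) = sqrt(K(r)/pi). Under CSR K(r) = pi r^2 and L(r) - r = 0.
    """
    points = _as_points(points)
    if len(points) < 2:
        raise UndefinedStatisticError("Ripley's K needs at least 2 points")
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ParameterError("radii must be positive")
    if geometry.is_toroidal and radii.max() > min(geometry.width, geometry.height) / 2:
        raise ParameterError("max radius exceeds the valid toroidal correction range")
    edges = np.concatenate([[0.0], radii])
    pair_counts, n_centers = _pair_counts(points, geometry, edges, edge_mode)
    cum = np.cumsum(pair_counts)
    lam = len(points) / geometry.area_nm2
    k = cum / (n_centers * lam)
    l_minus_r = np.sqrt(k / np.pi) - radii
    return (
        SpatialCurve(radii, k, "ripley_k", edge_mode),
        SpatialCurve(radii, l_minus_r, "ripley_l_minus_r", edge_mode),
    )


@dataclass
class VoronoiResult:
    """Per-point Voronoi cell areas (nm^2); NaN marks excluded unbounded cells."""

    areas: np.ndarray
    bounded: np.ndarray

    @property
    def finite_areas(self) -> np.ndarray:
        return self.areas[self.bounded]


def _polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area of a convex cell (vertices sorted by angle about the centroid)."""
    c = vertices.mean(axis=0)
    order = np.argsort(np.arctan2(vertices[:, 1] - c[1], vertices[:, 0] - c[0]))
    v = vertices[order]
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def voronoi_areas(points: np.ndarray, geometry: FieldGeometry) -> VoronoiResult:
    """Voronoi cell area of each point.

    Toroidal fields are handled by tessellating the 3x3 periodic tiling and
    reading areas off the central copy, so every cell is bounded and the
    areas partition the field exactly. Open fields exclude (flag) cells that
    are unbounded.
    """
    points = _as_points(points)
    if len(points) < 4:
        raise UndefinedStatisticError("Voronoi tessellation needs at least 4 points")
    if geometry.is_toroidal:
        box = np.array([geometry.width, geometry.height])
        pts = np.mod(points, box)
        offsets = [np.array([i, j]) * box for i in (-1, 0, 1) for j in (-1, 0, 1)]
        tiled = np.vstack([pts + off for off in offsets])
        central = np.arange(len(pts)) + 4 * len(pts)  # offsets list order: (0,0) is index 4
        try:
            vor = Voronoi(tiled)
        except QhullError as exc:
            raise UndefinedStatisticError(f"degenerate tessellation: {exc}") from exc
        areas = np.empty(len(pts))
        for out_i, i in enumerate(central):
            region = vor.regions[vor.point_region[i]]
            if -1 in region or len(region) == 0:  # pragma: no cover - cannot happen on a full tiling
                raise UndefinedStatisticError("unbounded central cell on a toroidal tiling")
            areas[out_i] = _polygon_area(vor.vertices[region])
        return VoronoiResult(areas, np.ones(len(pts), dtype=bool))
    try:
        vor = Voronoi(points)
    except QhullError as exc:
        raise UndefinedStatisticError(f"degenerate tessellation: {exc}") from exc
    areas = np.full(len(points), np.nan)
    bounded = np.zeros(len(points), dtype=bool)
    for i in range(len(points)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) == 0:
            continue
        areas[i] = _polygon_area(vor.vertices[region])
        bounded[i] = True
    return VoronoiResult(areas, bounded)
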