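"""Per-cluster and per-field quantities derived from a cluster assignment.

The chain of quantities mirrors single-molecule counting practice:
cluster density (clusters per um^2 of membrane), mean blinks per cluster,
copy number as the ratio of mean blinks to the blink count of isolated
single "background" antibodies, copies per um^2, total molecules per cell,
and the attachment fraction as the ratio of post- to pre-crosslinking
cluster densities. The overlay analysis recenters every qualifying
cluster's blinks on its centroid and fits a Gaussian to each axis of the
pooled displacement histogram; FWHM = 2*sqrt(2 ln 2) * sigma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .clustering import NOISE, ClusterAssignment, cluster_hull_area
from .errors import FitError, ParameterError, UndefinedStatisticError

GAUSS_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))  # ~2.3548


@dataclass
class ClusterStats:
    """Summary of one final cluster."""

    label: int
    n_blinks: int
    centroid: Tuple[float, float]
    radial_sd: float  # per-axis pooled SD about the centroid, nm
    hull_area: float  # nm^2


@dataclass
class FieldSummary:
    """Field-level quantities; the unit of statistical comparison is one field (cell)."""

    n_clusters: int
    region_area_um2: float
    cluster_density: float  # clusters / um^2
    mean_blinks: float
    sem_blinks: float
    sd_blinks: float
    background_blinks: Optional[float] = None
    copies_per_cluster: Optional[float] = None
    copies_density: Optional[float] = None
    fwhm_x: Optional[float] = None
    fwhm_y: Optional[float] = None
    params: Optional[dict] = None

    def to_dict(self) -> dict:
        return asdict(self)


def cluster_stats(assignment: ClusterAssignment) -> List[ClusterStats]:
    """One entry per final cluster, noise excluded."""
    points = assignment.source.points()
    out: List[ClusterStats] = []
    for lab in assignment.final_labels_present():
        pts = points[assignment.final_label == lab]
        centroid = pts.mean(axis=0)
        var = pts.var(axis=0)  # population variance per axis
        out.append(
            ClusterStats(
                label=int(lab),
                n_blinks=len(pts),
                centroid=(float(centroid[0]), float(centroid[1])),
                radial_sd=float(np.sqrt(var.mean())),
                hull_area=cluster_hull_area(pts),
            )
        )
    return out


def cluster_density(assignment: ClusterAssignment, region_area_um2: float) -> float:
    """Final clusters per um^2 of the analysis region."""
    if region_area_um2 <= 0:
        raise ParameterError("region area must be positive")
    return assignment.n_final_clusters / region_area_um2


def mean_blinks(stats: List[ClusterStats]) -> Tuple[float, float]:
    """Mean and SEM (SD/sqrt(n)) of blinks per cluster."""
    if not stats:
        raise UndefinedStatisticError("mean blinks undefined for an empty cluster list")
    counts = np.array([s.n_blinks for s in stats], dtype=float)
    sem = 0.0 if len(counts) == 1 else float(counts.std(ddof=1) / math.sqrt(len(counts)))
    return float(counts.mean()), sem


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def copy_number(mean_blinks: float, background_blinks: float) -> Tuple[float, int]:
    """Copies per cluster: mean blinks over the single-antibody background.

    Returns the raw ratio and the nearest-integer report (half away from zero).
    """
    if background_blinks <= 0:
        raise ParameterError("background blink count must be positive")
    ratio = mean_blinks / background_blinks
    return ratio, _round_half_away(ratio)


def copies_density(cluster_density: float, copies_per_cluster: float) -> float:
    """Copies per um^2 = cluster density x copies per cluster."""
    if cluster_density < 0 or copies_per_cluster < 0:
        raise ParameterError("inputs must be nonnegative")
    return cluster_density * copies_per_cluster


def round_sig(x: float, sig: int = 2) -> float:
    if x == 0:
        return 0.0
    return float(round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1)))


def total_per_cell(copies_density: float, surface_area_um2: float) -> Tuple[float, float]:
    """Molecules per cell; returns the product and its 2-significant-figure report."""
    if copies_density < 0 or surface_area_um2 < 0:
        raise ParameterError("inputs must be nonnegative")
    total = copies_density * surface_area_um2
    return total, round_sig(total, 2)


def attachment_fraction(final_density: float, initial_density: float) -> Tuple[float, int]:
    """Percent of clusters surviving crosslinking: 100 x final/initial.

    Interpreted as the cytoskeleton-anchored fraction of the protein.
    Returns the percentage and its nearest-integer report.
    """
    if initial_density <= 0:
        raise ParameterError("initial density must be positive")
    pct = 100.0 * final_density / initial_density
    return pct, _round_half_away(pct)


def overlay_clusters(
    assignment: ClusterAssignment,
    min_blinks: int = 3,
    correct_shrinkage: bool = False,
) -> np.ndarray:
    """Pool centroid-centered blink displacements over qualifying clusters.

    Centering on the empirical centroid shrinks the per-axis variance of an
    n-blink cluster by (1 - 1/n); with ``correct_shrinkage`` each cluster's
    displacements are rescaled by sqrt(n/(n-1)) to undo this.
    """
    points = assignment.source.points()
    chunks = []
    for lab in assignment.final_labels_present():
        pts = points[assignment.final_label == lab]
        n = len(pts)
        if n < min_blinks:
            continue
        disp = pts - pts.mean(axis=0)
        if correct_shrinkage and n > 1:
            disp = disp * math.sqrt(n / (n - 1))
        chunks.append(disp)
    if not chunks:
        raise UndefinedStatisticError(f"no cluster has at least {min_blinks} blinks")
    return np.vstack(chunks)


def _gaussian(x, amp, mu, sigma):
    return amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def fit_fwhm(displacements: np.ndarray, axis: str = "x", bin_width: float = 1.0) -> float:
    """Least-squares Gaussian fit to the displacement histogram of one axis.

    Displacements are binned in ``bin_width``-nm bins over +/- 5 SD; the
    fitted sigma is converted to FWHM = 2*sqrt(2 ln 2)*sigma.
    """
    displacements = np.asarray(displacements, dtype=float)
    if displacements.ndim == 2:
        col = {"x": 0, "y": 1}.get(axis)
        if col is None:
            raise ParameterError(f"axis must be 'x' or 'y', got {axis!r}")
        values = displacements[:, col]
    else:
        values = displacements
    if len(values) < 50:
        raise ParameterError("need at least 50 displacements for a stable fit")
    sd = values.std()
    if sd == 0:
        raise FitError("displacement distribution is degenerate (zero spread)")
    half = 5.0 * sd
    edges = np.arange(-half, half + bin_width, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p0 = (counts.max(), 0.0, sd)
    try:
        popt, _ = curve_fit(_gaussian, centers, counts, p0=p0, maxfev=10_000)
    except RuntimeError as exc:  # pragma: no cover - scipy reports non-convergence this way
        raise FitError(f"Gaussian fit did not converge: {exc}") from exc
    sigma = abs(float(popt[2]))
    if not np.isfinite(sigma) or sigma == 0:
        raise FitError("Gaussian fit produced a degenerate width")
    return GAUSS_FWHM_FACTOR * sigma


def summarize_field(
    assignment: ClusterAssignment,
    region_area_um2: Optional[float] = None,
    background_blinks: Optional[float] = None,
    min_overlay_blinks: int = 3,
    fit_overlay: bool = True,
    params: Optional[dict] = None,
) -> FieldSummary:
    """Assemble the standard field-level report from one assignment."""
    if region_area_um2 is None:
        region_area_um2 = assignment.source.geometry.area_um2
    stats = cluster_stats(assignment)
    n_clusters = len(stats)
    density = cluster_density(assignment, region_area_um2)
    if stats:
        mean_b, sem_b = mean_blinks(stats)
        counts = np.array([s.n_blinks for s in stats], dtype=float)
        sd_b = float(counts.std(ddof=1)) if len(counts) > 1 else 0.0
    else:
        mean_b = sem_b = sd_b = float("nan")
    summary = FieldSummary(
        n_clusters=n_clusters,
        region_area_um2=region_area_um2,
        cluster_density=density,
        mean_blinks=mean_b,
        sem_blinks=sem_b,
        sd_blinks=sd_b,
        background_blinks=background_blinks,
        params=params,
    )
    if background_blinks is not None and stats:
        ratio, _ = copy_number(mean_b, background_blinks)
        summary.copies_per_cluster = ratio
        summary.copies_density = copies_density(density, ratio)
    if fit_overlay and stats:
        try:
            disp = overlay_clusters(assignment, min_overlay_blinks, correct_shrinkage=True)
            summary.fwhm_x = fit_fwhm(disp, "x")
            summary.fwhm_y = fit_fwhm(disp, "y")
        except (UndefinedStatisticError, ParameterError, FitError):
            pass  # small fields simply omit the overlay fit
    return summary
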