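"""Axial-view ring quantification.

Rings of super-resolved puncta are reduced to a center (algebraic Kåsa circle
fit refined by one geometric Gauss–Newton pass), per-punctum radii and mean
diameter, a polar-unwrapped angular-occupancy profile with a completeness
fraction and gap arcs, and a nine-fold symmetry score (the mode-9 power ratio
of the punctum angles).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import DBSCAN

from ._utils import as_xy, wrap_angle
from . import stats as _stats

DEFAULT_BIN_WIDTH = np.deg2rad(10.0)


@dataclass
class RingFit:
    """Ring geometry summary.  ``mean_diameter = 2 * mean(radii)``."""

    center: np.ndarray
    radii: np.ndarray
    mean_diameter: float
    radius_sd: float
    n_puncta: int
    fit_method: str = "kasa+gn"

    def to_dict(self) -> dict:
        return {
            "center": [float(self.center[0]), float(self.center[1])],
            "radii": [float(r) for r in self.radii],
            "mean_diameter": float(self.mean_diameter),
            "radius_sd": float(self.radius_sd),
            "n_puncta": int(self.n_puncta),
            "fit_method": self.fit_method,
        }


@dataclass
class AngularOccupancy:
    """Polar-unwrapped ring occupancy.

    ``completeness + missing_fraction == 1``; gap arcs are contiguous runs of
    unoccupied bins given as (start angle, extent) in radians.
    """

    bin_width: float
    occupied: np.ndarray  # boolean mask per bin
    completeness: float
    missing_fraction: float
    gap_arcs: list
    n_localizations: int
    bin_counts: np.ndarray
    threshold: float

    def to_dict(self) -> dict:
        return {
            "bin_width": float(self.bin_width),
            "occupied": [bool(b) for b in self.occupied],
            "completeness": float(self.completeness),
            "missing_fraction": float(self.missing_fraction),
            "gap_arcs": [[float(a), float(b)] for a, b in self.gap_arcs],
            "n_localizations": int(self.n_localizations),
            "threshold": float(self.threshold),
        }


def cluster_puncta(table, radius: float = 12.0, min_count: int = 8) -> np.ndarray:
    """Group localizations into puncta by density and return centroids.

    A punctum is a DBSCAN cluster (eps=``radius``, min_samples=``min_count``);
    unclustered localizations are discarded as background.  Two true clusters
    closer than the grouping radius merge into one punctum — documented
    behaviour of density-based grouping.
    """
    xy = as_xy(table)
    if xy.shape[0] == 0:
        raise ValueError("no localizations to cluster; lower min_count or radius")
    labels = DBSCAN(eps=radius, min_samples=min_count).fit_predict(xy)
    ids = np.unique(labels[labels >= 0])
    if ids.size == 0:
        raise ValueError(
            "no puncta found; consider lowering min_count or increasing radius"
        )
    return np.vstack([xy[labels == i].mean(axis=0) for i in ids])


def _kasa_center(xy: np.ndarray) -> np.ndarray:
    x, y = xy[:, 0], xy[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x * x + y * y
    if np.linalg.matrix_rank(A - A.mean(axis=0)) < 2:
        raise ValueError("points are collinear or degenerate; cannot fit a circle")
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol[:2]


def _trim_outliers(xy: np.ndarray, center: np.ndarray, factor: float = 3.0):
    """Keep points whose radius lies within ``factor`` robust sds of the
    median radius (guards the algebraic fit against background points,
    which otherwise have enormous leverage)."""
    radii = np.linalg.norm(xy - center, axis=1)
    med = np.median(radii)
    mad_sd = 1.4826 * np.median(np.abs(radii - med))
    if mad_sd <= 0:
        return xy
    keep = np.abs(radii - med) <= factor * mad_sd
    return xy[keep] if keep.sum() >= 3 else xy


def fit_ring_center(points, refine: bool = True, robust: bool = True) -> np.ndarray:
    """Circle-fit center: algebraic Kåsa solution followed by geometric
    Gauss–Newton refinement on (cx, cy, r).

    With ``robust=True`` (default) the Kåsa stage is iterated with
    radius-outlier trimming so that sparse background localizations cannot
    drag the center; the fit remains exact for noiseless arcs.
    """
    xy = as_xy(points)
    if xy.shape[0] < 3:
        raise ValueError("at least 3 points are required to fit a circle")
    center = _kasa_center(xy)
    work = xy
    if robust:
        for _ in range(3):
            trimmed = _trim_outliers(xy, center)
            new_center = _kasa_center(trimmed)
            if np.linalg.norm(new_center - center) < 1e-9:
                center = new_center
                work = trimmed
                break
            center = new_center
            work = trimmed
    if refine:
        d = np.linalg.norm(work - center, axis=1)
        r = d.mean()
        for _ in range(10):
            dx = work[:, 0] - center[0]
            dy = work[:, 1] - center[1]
            d = np.hypot(dx, dy)
            d = np.where(d == 0, 1e-12, d)
            J = np.column_stack([-dx / d, -dy / d, -np.ones_like(d)])
            resid = d - r
            step, *_ = np.linalg.lstsq(J, -resid, rcond=None)
            center = center + step[:2]
            r = r + step[2]
            if np.linalg.norm(step) < 1e-10:
                break
    return center


def measure_diameter(points, center=None, fit_method: str = "kasa+gn") -> RingFit:
    """Per-point radii about the center; mean diameter = 2 x mean radius.

    ``points`` may be punctum centroids (the default analysis path, matching
    the punctum-based definition of the radius) or raw localizations.  No
    noise-bias correction is applied to the mean radius.
    """
    xy = as_xy(points)
    if center is None:
        center = fit_ring_center(xy)
    center = np.asarray(center, dtype=float)
    radii = np.linalg.norm(xy - center, axis=1)
    return RingFit(
        center=center,
        radii=radii,
        mean_diameter=float(2.0 * radii.mean()),
        radius_sd=float(radii.std(ddof=1)) if radii.size > 1 else 0.0,
        n_puncta=int(radii.size),
        fit_method=fit_method,
    )


def annulus_gate(points, center, sd_factor: float = 3.0) -> np.ndarray:
    """Restrict points to an annulus around the ring: median radius plus or
    minus ``sd_factor`` robust (MAD-based) radius sds.  Excludes background
    before angular or radial statistics."""
    xy = as_xy(points)
    center = np.asarray(center, dtype=float)
    radii = np.linalg.norm(xy - center, axis=1)
    med = np.median(radii)
    mad_sd = 1.4826 * np.median(np.abs(radii - med))
    if mad_sd <= 0:
        return xy
    return xy[np.abs(radii - med) <= sd_factor * mad_sd]


def angular_occupancy(table, center, bin_width: float = DEFAULT_BIN_WIDTH,
                      occupancy_threshold: float | None = None,
                      annulus_sd_factor: float = 3.0) -> AngularOccupancy:
    """Circular expansion of the ring along the polar coordinate.

    Localizations are gated to an annulus (median radius +- ``annulus_sd_factor``
    x radius sd) to exclude background, binned by angle (default 10 deg / bin),
    and a bin counts as occupied when its count reaches the threshold
    (default: 10% of the median nonzero-bin count, at least 3).  Completeness
    is the occupied-bin fraction; contiguous unoccupied runs are gap arcs.
    """
    xy = as_xy(table)
    center = np.asarray(center, dtype=float)
    xy = annulus_gate(xy, center, sd_factor=annulus_sd_factor)
    rel = xy - center
    theta = wrap_angle(np.arctan2(rel[:, 1], rel[:, 0]))
    n_bins = int(round(2.0 * np.pi / bin_width))
    counts, _ = np.histogram(theta, bins=n_bins, range=(0.0, 2.0 * np.pi))
    nonzero = counts[counts > 0]
    if occupancy_threshold is None:
        occupancy_threshold = max(3.0, 0.1 * (np.median(nonzero) if nonzero.size else 0.0))
    occupied = counts >= occupancy_threshold
    completeness = float(occupied.mean())
    gap_arcs = _circular_runs(~occupied, bin_width)
    return AngularOccupancy(
        bin_width=2.0 * np.pi / n_bins,
        occupied=occupied,
        completeness=completeness,
        missing_fraction=1.0 - completeness,
        gap_arcs=gap_arcs,
        n_localizations=int(theta.size),
        bin_counts=counts,
        threshold=float(occupancy_threshold),
    )


def _circular_runs(mask: np.ndarray, bin_width: float) -> list:
    """Contiguous True runs on a circular bin mask as (start, extent) arcs."""
    n = mask.size
    if mask.all():
        return [(0.0, 2.0 * np.pi)]
    if not mask.any():
        return []
    # rotate so the mask starts on a False bin, then scan linearly
    start_idx = int(np.argmin(mask))
    rolled = np.roll(mask, -start_idx)
    arcs = []
    i = 0
    while i < n:
        if rolled[i]:
            j = i
            while j < n and rolled[j]:
                j += 1
            arcs.append((wrap_angle((start_idx + i) * bin_width), (j - i) * bin_width))
            i = j
        else:
            i += 1
    return arcs


def symmetry_score(puncta, center=None):
    """Punctum count and mode-9 power ratio.

    The ratio is ``|sum_j exp(i * 9 * theta_j)|^2 / n^2`` over punctum angles:
    1 for perfect nine-fold placement, expectation 1/n under uniform angles.
    ``puncta`` may be centroids (with ``center``) or raw angles in radians.
    """
    arr = np.asarray(puncta, dtype=float)
    if arr.ndim == 2:
        center = np.zeros(2) if center is None else np.asarray(center, dtype=float)
        rel = arr - center
        theta = np.arctan2(rel[:, 1], rel[:, 0])
    else:
        theta = arr
    n = theta.size
    if n < 1:
        raise ValueError("at least one punctum is required")
    phasor = np.exp(1j * 9.0 * theta).sum()
    return n, float(np.abs(phasor) ** 2 / n ** 2)


def radial_spread_stat(group_a_sds, group_b_sds) -> "_stats.GroupComparison":
    """Compare per-centriole radial spreads (radius sd) between two
    conditions with a two-sided Mann–Whitney U test."""
    return _stats.compare(group_a_sds, group_b_sds)
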