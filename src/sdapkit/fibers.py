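"""Microtubule-fiber detection and counting around the mother centriole.

Fibers are elongated density clusters of alpha-tubulin localizations: a
cluster qualifies when its principal-axis elongation is at least 4:1, its
span reaches the minimum length and it carries enough supporting
localizations.  Census statistics are the fiber rate per radian around a
ring center (axial view) and per-longitudinal-bin counts along the centriole
axis (lateral view); in both cases a fiber is assigned by its
centriole-proximal anchor endpoint.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import DBSCAN

from ._utils import as_xy
from .lateral import CentrioleAxis


@dataclass
class FiberSegment:
    """A straight fiber: principal-axis span of an elongated cluster."""

    p0: np.ndarray
    p1: np.ndarray
    n_support: int
    orientation: float  # radians
    length: float

    def endpoints(self) -> np.ndarray:
        return np.vstack([self.p0, self.p1])

    def to_dict(self) -> dict:
        return {
            "p0": [float(v) for v in self.p0],
            "p1": [float(v) for v in self.p1],
            "n_support": int(self.n_support),
            "orientation": float(self.orientation),
            "length": float(self.length),
        }


@dataclass
class FiberCensus:
    segments: list
    rate_per_radian: float | None = None
    bin_edges: np.ndarray | None = None
    bin_counts: np.ndarray | None = None


def _pca_segment(pts: np.ndarray, min_length: float, min_support: int,
                 min_elongation: float) -> FiberSegment | None:
    """Segment from the principal-axis span, or None if the point set is not
    an elongated fiber."""
    if pts.shape[0] < min_support:
        return None
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if np.sqrt(evals[0] / max(evals[1], 1e-12)) < min_elongation:
        return None
    axis = evecs[:, 0]
    proj = (pts - centroid) @ axis
    length = float(proj.max() - proj.min())
    if length < min_length:
        return None
    return FiberSegment(
        p0=centroid + proj.min() * axis,
        p1=centroid + proj.max() * axis,
        n_support=int(pts.shape[0]),
        orientation=float(np.arctan2(axis[1], axis[0])),
        length=length,
    )


def _hough_extract(pts: np.ndarray, min_length: float, min_support: int,
                   min_elongation: float, line_tol: float = 50.0,
                   n_angles: int = 90) -> list[FiberSegment]:
    """Deterministic Hough-style extraction of straight fibers from a merged
    cluster: vote over quantized orientations/offsets, peel off the strongest
    line, refine its direction by PCA of the accepted points, repeat."""
    segments: list[FiberSegment] = []
    angles = np.linspace(0.0, np.pi, n_angles, endpoint=False)
    normals = np.column_stack([-np.sin(angles), np.cos(angles)])  # (A, 2)
    bin_w = 25.0
    while pts.shape[0] >= min_support:
        offsets = pts @ normals.T  # (n, A)
        best_votes, best_ai, best_off = -1, 0, 0.0
        for ai in range(n_angles):
            o = offsets[:, ai]
            lo = o.min()
            nb = max(1, int((o.max() - lo) / bin_w) + 1)
            hist, edges = np.histogram(o, bins=nb, range=(lo, lo + nb * bin_w))
            bi = int(np.argmax(hist))
            if hist[bi] > best_votes:
                best_votes, best_ai = int(hist[bi]), ai
                best_off = 0.5 * (edges[bi] + edges[bi + 1])
        if best_votes < max(5, min_support // 3):
            break
        sel = np.abs(offsets[:, best_ai] - best_off) <= line_tol
        sub = pts[sel]
        if sub.shape[0] >= 3:  # refine direction and membership once
            _, evecs, centroid = _pca_of(sub)
            normal = evecs[:, 1]
            dist = np.abs((pts - centroid) @ normal)
            sel = dist <= line_tol
            sub = pts[sel]
        seg = _pca_segment(sub, min_length, min_support, min_elongation)
        if seg is None:
            break
        segments.append(seg)
        pts = pts[~sel]
    return segments


def _pca_of(pts: np.ndarray):
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return evals[order], evecs[:, order], centroid


def detect_fiber_segments(table, min_length: float = 300.0, min_support: int = 30,
                          min_elongation: float = 4.0,
                          gap_radius: float = 50.0) -> list[FiberSegment]:
    """Group localizations into elongated clusters and return fiber segments.

    ``gap_radius`` is the DBSCAN bridging radius: gaps along a fiber smaller
    than it are crossed, so a fiber split by a sub-``gap_radius`` gap counts
    once.  A connected component that is itself straight yields one segment;
    a component formed by crossing fibers is decomposed into individual
    straight lines by a deterministic Hough vote.  The empty list is a valid
    result.
    """
    xy = as_xy(table)
    if xy.shape[0] == 0:
        return []
    labels = DBSCAN(eps=gap_radius, min_samples=5).fit_predict(xy)
    segments = []
    for label in np.unique(labels[labels >= 0]):
        pts = xy[labels == label]
        if pts.shape[0] < min_support:
            continue
        seg = _pca_segment(pts, min_length, min_support, min_elongation)
        if seg is not None:
            segments.append(seg)
        else:
            segments.extend(_hough_extract(pts, min_length, min_support,
                                           min_elongation))
    return segments


def _anchor_endpoint(segment: FiberSegment, center: np.ndarray) -> np.ndarray:
    ends = segment.endpoints()
    dists = np.linalg.norm(ends - center, axis=1)
    return ends[int(np.argmin(dists))]


def count_per_radian(segments, center, annulus,
                     angular_extent: float = 2.0 * np.pi) -> float:
    """Fibers per radian: segments whose centriole-proximal endpoint falls in
    the annulus, divided by the surveyed angular extent."""
    center = np.asarray(center, dtype=float)
    r_in, r_out = annulus
    count = 0
    for seg in segments:
        anchor = _anchor_endpoint(seg, center)
        r = np.linalg.norm(anchor - center)
        if r_in <= r <= r_out:
            count += 1
    return count / angular_extent


def count_per_longitudinal_bin(segments, axis: CentrioleAxis, bin_edges):
    """Per-bin fiber counts along the centriole axis.

    Each fiber is assigned to the bin containing the longitudinal coordinate
    of its axis-proximal endpoint (the endpoint nearer the centriole axis
    line).  Returns (bin_edges, counts).
    """
    bin_edges = np.asarray(bin_edges, dtype=float)
    counts = np.zeros(bin_edges.size - 1, dtype=int)
    perp = np.array([-axis.direction[1], axis.direction[0]])
    for seg in segments:
        ends = seg.endpoints()
        trans = np.abs((ends - axis.origin) @ perp)
        anchor = ends[int(np.argmin(trans))]
        longi = float((anchor - axis.origin) @ axis.direction)
        idx = np.searchsorted(bin_edges, longi, side="right") - 1
        if 0 <= idx < counts.size:
            counts[idx] += 1
    return bin_edges, counts


def build_census(segments, center=None, annulus=None, axis=None,
                 bin_edges=None) -> FiberCensus:
    """Assemble a fiber census with whichever statistics the inputs allow."""
    census = FiberCensus(segments=list(segments))
    if center is not None and annulus is not None:
        census.rate_per_radian = count_per_radian(segments, center, annulus)
    if axis is not None and bin_edges is not None:
        edges, counts = count_per_longitudinal_bin(segments, axis, bin_edges)
        census.bin_edges = edges
        census.bin_counts = counts
    return census
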