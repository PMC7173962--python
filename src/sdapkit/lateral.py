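"""Lateral-view analyses: centriole-axis estimation, longitudinal profiling
relative to the reference layer, layer detection, composite averaging and ROI
densities.

Longitudinal coordinates are signed: the reference protein layer (SCLT1 in
the standard two-color experiment) defines zero, the distal direction is
positive and proximal is negative.  The reference ring appears as a rod in
the lateral view; its long axis is transverse to the centriole, so the
centriole axis is the perpendicular through the rod centroid.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from ._utils import as_xy, principal_axes, robust_principal_axes
from .synthetic import DEFAULT_LOCALIZATION_SD

AXIAL_MAX_RATIO = 1.8
LATERAL_MIN_RATIO = 3.0


@dataclass
class CentrioleAxis:
    """Signed centriole axis: origin at the reference centroid, unit
    direction pointing proximal -> distal."""

    origin: np.ndarray
    direction: np.ndarray
    view: str = "lateral"

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(d)
        if norm == 0:
            raise ValueError("axis direction must be nonzero")
        self.direction = d / norm

    def project(self, points):
        """Return (longitudinal, transverse) coordinates of points."""
        xy = as_xy(points) - self.origin
        longi = xy @ self.direction
        perp = np.array([-self.direction[1], self.direction[0]])
        return longi, xy @ perp


@dataclass
class Layer:
    position: float
    width: float
    prominence: float

    def to_dict(self) -> dict:
        return {"position": float(self.position), "width": float(self.width),
                "prominence": float(self.prominence)}


@dataclass
class LongitudinalProfile:
    """Axis-projected localization density.

    ``density`` has units localizations/nm so that sum(density)*bin_width
    equals the localization count.  Raw projections are retained for
    quantile statistics.
    """

    bin_centers: np.ndarray
    density: np.ndarray
    bin_width: float
    n: int
    projections: np.ndarray | None = None
    layers: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "bin_centers": [float(c) for c in self.bin_centers],
            "density": [float(d) for d in self.density],
            "bin_width": float(self.bin_width),
            "n": int(self.n),
            "layers": [l.to_dict() for l in self.layers],
        }


def classify_view(reference, min_localizations: int = 50) -> str:
    """Classify the reference point cloud: ``axial`` (ring, principal-axis
    eigenvalue ratio near 1), ``lateral`` (rod, ratio >= 3) or ``ambiguous``."""
    xy = as_xy(reference)
    if xy.shape[0] < min_localizations:
        raise ValueError(
            f"need >= {min_localizations} reference localizations, got {xy.shape[0]}"
        )
    evals, _, _ = robust_principal_axes(xy)
    ratio = evals[0] / max(evals[1], 1e-12)
    if ratio < AXIAL_MAX_RATIO:
        return "axial"
    if ratio >= LATERAL_MIN_RATIO:
        return "lateral"
    return "ambiguous"


def estimate_axis(reference, distal_marker=None, distal_direction=None,
                  target=None, reference_is_distal: bool = False) -> CentrioleAxis:
    """Estimate the signed centriole axis from the reference channel.

    For a rod-shaped reference (the ring viewed side-on) the axis is the
    perpendicular to the rod's long axis through its centroid.  For a compact
    reference (e.g. a distal-cap marker), an elongated ``target`` cloud
    supplies the axis direction instead.  The distal sign must be fixed by a
    ``distal_marker`` point cloud, an explicit ``distal_direction`` hint
    vector, or ``reference_is_distal`` (compact reference at the distal end);
    otherwise the orientation is unidentifiable and an error is raised.
    """
    xy = as_xy(reference)
    evals, evecs, centroid = robust_principal_axes(xy)
    ratio = evals[0] / max(evals[1], 1e-12)
    if ratio >= LATERAL_MIN_RATIO:
        rod_axis = evecs[:, 0]
        direction = np.array([-rod_axis[1], rod_axis[0]])
    elif target is not None:
        t_xy = as_xy(target)
        t_evals, t_evecs, _ = robust_principal_axes(t_xy)
        if t_evals[0] / max(t_evals[1], 1e-12) < LATERAL_MIN_RATIO:
            raise ValueError("target cloud is not elongated; cannot orient the axis")
        direction = t_evecs[:, 0]
    else:
        raise ValueError(
            "reference cloud is not rod-like (ambiguous view); provide a "
            "lateral-view reference or an elongated target cloud"
        )
    direction = direction / np.linalg.norm(direction)

    if distal_marker is not None:
        marker_c = as_xy(distal_marker).mean(axis=0)
        if (marker_c - centroid) @ direction < 0:
            direction = -direction
    elif distal_direction is not None:
        hint = np.asarray(distal_direction, dtype=float)
        if hint @ direction < 0:
            direction = -direction
    elif reference_is_distal and target is not None:
        t_centroid = as_xy(target).mean(axis=0)
        if (t_centroid - centroid) @ direction > 0:
            direction = -direction
    else:
        raise ValueError(
            "distal orientation is unidentifiable: provide distal_marker, "
            "distal_direction, or reference_is_distal with a target cloud"
        )
    return CentrioleAxis(origin=centroid, direction=direction)


def longitudinal_profile(target, axis: CentrioleAxis,
                         bin_width: float = 10.0) -> LongitudinalProfile:
    """Histogram of target localizations projected on the centriole axis."""
    longi, _ = axis.project(target)
    lo = np.floor(longi.min() / bin_width) * bin_width
    hi = np.ceil(longi.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    n_bins = int(round((hi - lo) / bin_width))
    counts, edges = np.histogram(longi, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return LongitudinalProfile(
        bin_centers=centers,
        density=counts / bin_width,
        bin_width=float(bin_width),
        n=int(longi.size),
        projections=longi,
    )


def profile_from_density(bin_centers, density, bin_width: float) -> LongitudinalProfile:
    """Build a profile from an explicit density curve (analytic inputs)."""
    bin_centers = np.asarray(bin_centers, dtype=float)
    density = np.asarray(density, dtype=float)
    n = density.sum() * bin_width
    return LongitudinalProfile(bin_centers, density, float(bin_width),
                               int(round(n)), projections=None)


def detect_layers(profile: LongitudinalProfile, min_separation: float = 50.0,
                  min_prominence: float = 0.2,
                  kernel_sd: float = DEFAULT_LOCALIZATION_SD) -> list[Layer]:
    """Detect protein layers as peaks of the smoothed longitudinal profile.

    The density is smoothed with a Gaussian kernel (sd = localization
    precision by default); peaks closer than ``min_separation`` or with
    prominence below ``min_prominence`` x the maximum are suppressed.  Each
    layer position is the density centroid of the peak's +-FWHM window (more
    robust to binning than the argmax) and the width is the FWHM.
    """
    if profile.density.size == 0:
        return []
    density = np.asarray(profile.density, dtype=float)
    bw = profile.bin_width
    smoothed = gaussian_filter1d(density, sigma=max(kernel_sd / bw, 1e-9),
                                 mode="constant")
    if smoothed.max() <= 0:
        return []
    # pad so boundary maxima are detectable
    padded = np.concatenate([[0.0], smoothed, [0.0]])
    idx, props = find_peaks(
        padded,
        distance=max(1, int(round(min_separation / bw))),
        prominence=min_prominence * smoothed.max(),
    )
    layers = []
    centers = profile.bin_centers
    for peak, prom in zip(idx - 1, props["prominences"]):
        half = smoothed[peak] / 2.0
        left = peak
        while left > 0 and smoothed[left - 1] >= half:
            left -= 1
        right = peak
        while right < smoothed.size - 1 and smoothed[right + 1] >= half:
            right += 1
        window = slice(left, right + 1)
        weights = smoothed[window]
        position = float(np.average(centers[window], weights=weights))
        width = float((right - left + 1) * bw)
        layers.append(Layer(position=position, width=width, prominence=float(prom)))
    return sorted(layers, key=lambda l: l.position)


@dataclass
class CompositeImage:
    """Per-channel 2D histograms accumulated over aligned centrioles.

    Axes: x = transverse nm, y = longitudinal nm (distal positive); pixel
    size default 10 nm.  Total counts equal the sum of per-centriole counts
    inside the extent, and accumulation is order-independent.
    """

    channels: dict
    n_centrioles: int
    pixel_nm: float
    extent: tuple  # (xmin, xmax, ymin, ymax)

    @property
    def total(self) -> float:
        return float(sum(img.sum() for img in self.channels.values()))


def align_and_composite(centrioles, reference_channel: str,
                        distal_marker_channel: str | None = None,
                        pixel_nm: float = 10.0,
                        extent=(-600.0, 600.0, -700.0, 300.0)) -> CompositeImage:
    """Align lateral-view centrioles on their reference layer and sum their
    2D histograms.

    Each centriole is translated so the reference centroid sits at the
    origin and rotated so the centriole axis points to +y.  The transverse
    sign is canonicalized from the skewness of the reference transverse
    coordinates (pose-invariant); for symmetric references either choice
    yields the same histogram.
    """
    if not centrioles:
        raise ValueError("no centrioles to composite")
    xmin, xmax, ymin, ymax = extent
    nx = int(round((xmax - xmin) / pixel_nm))
    ny = int(round((ymax - ymin) / pixel_nm))
    sums: dict[str, np.ndarray] = {}
    for table in centrioles:
        ref = table.select_channel(reference_channel)
        if classify_view(ref) != "lateral":
            raise ValueError("composite alignment requires lateral-view centrioles")
        marker = (table.select_channel(distal_marker_channel)
                  if distal_marker_channel else None)
        if marker is not None and len(marker):
            axis = estimate_axis(ref, distal_marker=marker)
        else:
            # unsigned alignment: pick the sign that puts the bulk of the
            # non-reference signal on the proximal (negative) side
            axis = estimate_axis(ref, distal_direction=(0.0, 1.0))
            others = table.df[~table.df["channel"].isin([reference_channel])]
            if len(others):
                longi, _ = axis.project(others[["x", "y"]].to_numpy(dtype=float))
                if np.median(longi) > 0:
                    axis = CentrioleAxis(axis.origin, -axis.direction)
        _, trans_ref = axis.project(ref)
        # canonicalize the transverse sign from the reference skewness, but
        # only when the asymmetry is real (not floating-point noise)
        skew = float(np.mean(trans_ref ** 3))
        scale = float(np.mean(trans_ref ** 2)) ** 1.5
        flip = -1.0 if skew < -0.05 * scale else 1.0
        for channel in table.channels():
            sub = table.select_channel(channel)
            longi, trans = axis.project(sub)
            hist, _, _ = np.histogram2d(
                longi, flip * trans, bins=[ny, nx],
                range=[[ymin, ymax], [xmin, xmax]],
            )
            sums[channel] = sums.get(channel, np.zeros((ny, nx))) + hist
    return CompositeImage(channels=sums, n_centrioles=len(centrioles),
                          pixel_nm=float(pixel_nm), extent=tuple(extent))


def roi_density(table, axis: CentrioleAxis, longitudinal_range,
                radial_range) -> tuple[int, float]:
    """Localization count and count/area in a rectangular ROI given in
    (longitudinal, |transverse|) coordinates.

    The ROI covers both sides of the axis, so its area is
    ``(l1 - l0) * 2 * (t1 - t0)`` nm^2.  An empty ROI yields density 0.
    """
    l0, l1 = longitudinal_range
    t0, t1 = radial_range
    if l1 <= l0 or t1 < t0 or t0 < 0:
        raise ValueError("ROI ranges must be increasing and radial range non-negative")
    longi, trans = axis.project(table)
    inside = (longi >= l0) & (longi < l1) & (np.abs(trans) >= t0) & (np.abs(trans) < t1)
    count = int(inside.sum())
    area = (l1 - l0) * 2.0 * (t1 - t0)
    return count, count / area if area > 0 else 0.0


def distal_boundary(profile: LongitudinalProfile, quantile: float = 0.95) -> float:
    """Signed position below which the stated quantile of localizations lie
    (the distal-edge statistic used to compare spreading between conditions)."""
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    if profile.projections is not None and profile.projections.size:
        return float(np.quantile(profile.projections, quantile))
    # piecewise-linear CDF over the binned density
    weights = profile.density * profile.bin_width
    total = weights.sum()
    if total <= 0:
        raise ValueError("empty profile")
    cum = np.concatenate([[0.0], np.cumsum(weights)]) / total
    edges = np.concatenate([
        profile.bin_centers - profile.bin_width / 2.0,
        [profile.bin_centers[-1] + profile.bin_width / 2.0],
    ])
    return float(np.interp(quantile, cum, edges))
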