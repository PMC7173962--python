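"""Pre-analysis corrections: fiducial drift correction and chromatic
registration.

Drift is measured from fiducial beads that emit in (nearly) every frame and
is subtracted per localization, which is equivalent to the classical
rendered-image correlation approach in the noiseless limit and strictly
sharper with noise.  Chromatic aberration between the short- and
long-wavelength channels is modelled as a full second-order ("parabolic")
2D polynomial fitted on calibration-bead pairs and applied to the
short-wavelength channel only.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .localizations import LocalizationTable
from .synthetic import quadratic_features


# --------------------------------------------------------------------- drift


@dataclass
class DriftTrajectory:
    """Per-frame displacement (dx, dy) nm relative to frame 0."""

    displacement: np.ndarray  # (n_frames, 2)
    smoothing_window: int = 1

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.displacement.ndim != 2 or self.displacement.shape[1] != 2:
            raise ValueError("displacement must be an (n_frames, 2) array")
        if not np.allclose(self.displacement[0], 0.0, atol=1e-9):
            raise ValueError("frame-0 displacement must be (0, 0)")

    @property
    def n_frames(self) -> int:
        return self.displacement.shape[0]

    def negated(self) -> "DriftTrajectory":
        return DriftTrajectory(-self.displacement, self.smoothing_window)

    def to_dict(self) -> dict:
        return {"displacement": self.displacement.tolist(),
                "smoothing_window": int(self.smoothing_window)}

    @classmethod
    def from_dict(cls, d: dict) -> "DriftTrajectory":
        return cls(np.asarray(d["displacement"], dtype=float),
                   int(d.get("smoothing_window", 1)))


def _cluster_labels(xy: np.ndarray, eps: float, min_samples: int,
                    max_fit_points: int = 4000) -> np.ndarray:
    """DBSCAN labels; for large tables the fit runs on a deterministic
    subsample and the remaining points are assigned to the nearest labelled
    subsample point within ``eps`` (noise otherwise)."""
    n = xy.shape[0]
    if n <= max_fit_points:
        return DBSCAN(eps=eps, min_samples=min_samples).fit_predict(xy)
    idx = np.unique(np.linspace(0, n - 1, max_fit_points).astype(int))
    sub_labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(xy[idx])
    from scipy.spatial import cKDTree

    keep = sub_labels >= 0
    labels = np.full(n, -1, dtype=int)
    if keep.any():
        tree = cKDTree(xy[idx][keep])
        dist, nearest = tree.query(xy, k=1)
        ok = dist <= eps
        labels[ok] = sub_labels[keep][nearest[ok]]
    return labels


def detect_fiducials(table: LocalizationTable, min_frames_fraction: float = 0.5,
                     cluster_radius: float = 100.0, n_frames: int | None = None,
                     max_track_scatter: float = 50.0) -> dict[int, pd.DataFrame]:
    """Find fiducial-bead tracks: spatial clusters persistent across frames.

    A cluster qualifies when it is present in at least ``min_frames_fraction``
    of all frames and its per-frame positions wander smoothly (temporal
    scatter about a rolling median below ``max_track_scatter`` nm) — the
    latter rejects dense structural clusters that happen to span many frames.

    Returns ``{track_id: DataFrame indexed by frame with columns x, y}``.
    """
    if len(table) == 0:
        raise ValueError("empty localization table")
    if n_frames is None:
        n_frames = int(table.frames.max()) + 1
    labels = _cluster_labels(table.xy, eps=cluster_radius, min_samples=10)
    df = table.df.assign(_label=labels)
    tracks: dict[int, pd.DataFrame] = {}
    tid = 0
    for label, group in df[df["_label"] >= 0].groupby("_label"):
        per_frame = group.groupby("frame")[["x", "y"]].mean()
        if len(per_frame) < min_frames_fraction * n_frames:
            continue
        smooth = per_frame.rolling(101, center=True, min_periods=1).median()
        resid = (per_frame - smooth).to_numpy()
        scatter = float(np.sqrt(np.mean(resid ** 2)))
        if scatter > max_track_scatter:
            continue
        tracks[tid] = per_frame
        tid += 1
    if not tracks:
        raise ValueError(
            "no persistent fiducial cluster found; disable drift correction "
            "(drift=none) or supply fiducial coordinates manually"
        )
    return tracks


def estimate_drift(tracks: dict[int, pd.DataFrame], smoothing_window: int = 100,
                   n_frames: int | None = None) -> DriftTrajectory:
    """Average fiducial tracks into a smoothed drift trajectory.

    Per-frame displacement is the mean over tracks of (position(frame) -
    position(first frame)), linearly interpolated over missing frames and
    smoothed with a centered moving average of ``smoothing_window`` frames;
    the result is re-anchored so that frame 0 maps to (0, 0).
    """
    if not tracks:
        raise ValueError("at least one fiducial track is required")
    if n_frames is None:
        n_frames = max(int(t.index.max()) for t in tracks.values()) + 1
    full_index = pd.RangeIndex(n_frames)
    disps = []
    for track in tracks.values():
        rel = track - track.iloc[0]
        rel = rel.reindex(full_index).interpolate(limit_direction="both")
        disps.append(rel.to_numpy())
    mean_disp = np.mean(disps, axis=0)
    smoothed = (pd.DataFrame(mean_disp)
                .rolling(int(smoothing_window), center=True, min_periods=1)
                .mean().to_numpy())
    smoothed = smoothed - smoothed[0]
    return DriftTrajectory(smoothed, smoothing_window=int(smoothing_window))


def apply_drift(table: LocalizationTable, drift: DriftTrajectory) -> LocalizationTable:
    """Translate each localization by minus the displacement of its frame."""
    frames = table.frames
    if len(table) and frames.max() >= drift.n_frames:
        raise ValueError(
            f"table contains frame {frames.max()} but the trajectory only "
            f"covers frames 0..{drift.n_frames - 1}"
        )
    return table.with_xy(table.xy - drift.displacement[frames])


# ----------------------------------------------------------------- chromatic

_ORDER_NCOEF = {0: 1, 1: 3, 2: 6}


@dataclass
class ChromaticMap:
    """Fitted polynomial registration from short- onto long-channel nm
    coordinates.  ``coeffs_x``/``coeffs_y`` follow the
    ``(1, x, y, x^2, x*y, y^2)`` convention (higher terms zero for lower
    fit orders)."""

    coeffs_x: np.ndarray
    coeffs_y: np.ndarray
    residual_rms: float
    n_beads: int
    order: int = 2
    held_out_rms: float | None = None

    def __post_init__(self):
        self.coeffs_x = np.asarray(self.coeffs_x, dtype=float)
        self.coeffs_y = np.asarray(self.coeffs_y, dtype=float)

    def apply(self, xy: np.ndarray) -> np.ndarray:
        feats = quadratic_features(xy)
        return np.column_stack([feats @ self.coeffs_x, feats @ self.coeffs_y])

    def to_dict(self) -> dict:
        return {
            "coeffs_x": self.coeffs_x.tolist(),
            "coeffs_y": self.coeffs_y.tolist(),
            "residual_rms": float(self.residual_rms),
            "n_beads": int(self.n_beads),
            "order": int(self.order),
            "held_out_rms": None if self.held_out_rms is None else float(self.held_out_rms),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChromaticMap":
        return cls(np.asarray(d["coeffs_x"]), np.asarray(d["coeffs_y"]),
                   float(d["residual_rms"]), int(d["n_beads"]),
                   int(d.get("order", 2)), d.get("held_out_rms"))


def _solve_poly(short_xy: np.ndarray, long_xy: np.ndarray, order: int):
    ncoef = _ORDER_NCOEF[order]
    feats = quadratic_features(short_xy)[:, :ncoef]
    if np.linalg.matrix_rank(feats) < ncoef:
        raise ValueError(
            f"bead layout is degenerate for an order-{order} fit "
            f"(design matrix rank < {ncoef}); spread beads over the field"
        )
    cx, *_ = np.linalg.lstsq(feats, long_xy[:, 0], rcond=None)
    cy, *_ = np.linalg.lstsq(feats, long_xy[:, 1], rcond=None)
    full_x = np.zeros(6)
    full_y = np.zeros(6)
    full_x[:ncoef] = cx
    full_y[:ncoef] = cy
    return full_x, full_y


def fit_chromatic_map(short_xy: np.ndarray, long_xy: np.ndarray,
                      order: int = 2) -> ChromaticMap:
    """Least-squares polynomial registration of bead pairs.

    Residual RMS is computed per axis: sqrt(mean over beads and axes of the
    squared residual).  With >= 10 beads a leave-one-out held-out RMS is also
    reported.
    """
    short_xy = np.asarray(short_xy, dtype=float)
    long_xy = np.asarray(long_xy, dtype=float)
    if order not in _ORDER_NCOEF:
        raise ValueError("order must be 0, 1 or 2")
    n = short_xy.shape[0]
    if n < 6:
        raise ValueError(
            "at least 6 bead pairs are required to identify the 6-coefficient "
            "second-order chromatic mapping"
        )
    cx, cy = _solve_poly(short_xy, long_xy, order)
    feats = quadratic_features(short_xy)
    pred = np.column_stack([feats @ cx, feats @ cy])
    resid = pred - long_xy
    rms = float(np.sqrt(np.mean(resid ** 2)))
    held_out = None
    if n >= 10:
        errs = []
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            hx, hy = _solve_poly(short_xy[mask], long_xy[mask], order)
            f = quadratic_features(short_xy[i:i + 1])
            p = np.array([f @ hx, f @ hy]).ravel()
            errs.append(p - long_xy[i])
        held_out = float(np.sqrt(np.mean(np.asarray(errs) ** 2)))
    return ChromaticMap(cx, cy, rms, n, order, held_out)


def apply_chromatic_map(table: LocalizationTable, cmap: ChromaticMap,
                        channel: str) -> LocalizationTable:
    """Register the named channel onto the long-wavelength frame; other
    channels are untouched.  The channel argument is mandatory so that the
    long channel cannot be transformed by accident."""
    mask = (table.df["channel"] == str(channel)).to_numpy()
    xy = table.xy
    xy[mask] = cmap.apply(xy[mask])
    return table.with_xy(xy)
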