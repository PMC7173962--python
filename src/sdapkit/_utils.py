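"""Small shared numeric helpers."""
from __future__ import annotations

import numpy as np


def as_xy(obj) -> np.ndarray:
    """Coerce a LocalizationTable, DataFrame or (n, 2) array to float xy."""
    if hasattr(obj, "xy"):
        return np.asarray(obj.xy, dtype=float)
    if hasattr(obj, "columns"):  # DataFrame
        return np.asarray(obj[["x", "y"]], dtype=float)
    arr = np.asarray(obj, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"expected an (n, 2) coordinate array, got shape {arr.shape}")
    return arr


def rotation_matrix(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s], [s, c]])


def principal_axes(xy: np.ndarray):
    """Centered PCA of a 2D point cloud.

    Returns (eigenvalues descending, eigenvectors as columns, centroid).
    Eigenvalues are variances along the principal directions.
    """
    xy = np.asarray(xy, dtype=float)
    centroid = xy.mean(axis=0)
    cov = np.cov((xy - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return evals[order], evecs[:, order], centroid


def robust_principal_axes(xy: np.ndarray, gate: float = 4.0, n_iter: int = 2):
    """Principal axes after trimming far outliers (sparse background).

    Points farther than ``gate`` robust (MAD-based) sds from the median along
    either principal direction are dropped and the PCA recomputed.  Returns
    (eigenvalues, eigenvectors, centroid) of the trimmed cloud.
    """
    xy = np.asarray(xy, dtype=float)
    evals, evecs, centroid = principal_axes(xy)
    for _ in range(n_iter):
        proj = (xy - centroid) @ evecs
        med = np.median(proj, axis=0)
        mad_sd = 1.4826 * np.median(np.abs(proj - med), axis=0)
        mad_sd = np.where(mad_sd <= 0, np.inf, mad_sd)
        keep = np.all(np.abs(proj - med) <= gate * mad_sd, axis=1)
        if keep.sum() < 3 or keep.all():
            break
        xy = xy[keep]
        evals, evecs, centroid = principal_axes(xy)
    return evals, evecs, centroid


def wrap_angle(theta):
    """Wrap angles into [0, 2*pi)."""
    return np.mod(theta, 2.0 * np.pi)
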