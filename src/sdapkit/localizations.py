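"""Localization tables: the primary SMLM data product.

A localization table holds one row per detected single-fluorophore emission
with the acquisition frame, the imaging channel, the fitted position in nm and
the photon count.  Tables round-trip losslessly through CSV in either a
ThunderSTORM-style dialect (``"x [nm]"`` headers) or a plain ``generic``
dialect.  All coordinates are continuous nm with an arbitrary origin; pixels
appear only when rendering.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

REQUIRED_COLUMNS = ("frame", "channel", "x", "y", "photons")
ALL_COLUMNS = ("frame", "channel", "x", "y", "photons", "uncertainty")

#: header mapping for the ThunderSTORM CSV dialect
_THUNDERSTORM_HEADERS = {
    "frame": "frame",
    "channel": "channel",
    "x [nm]": "x",
    "y [nm]": "y",
    "intensity [photon]": "photons",
    "uncertainty [nm]": "uncertainty",
}
_NUMERIC_COLUMNS = ("frame", "x", "y", "photons", "uncertainty")


@dataclass(frozen=True)
class LocalizationTable:
    """Immutable wrapper around a localization DataFrame.

    Columns: ``frame`` (non-negative int), ``channel`` (string id), ``x``/``y``
    (nm), ``photons`` and optionally ``uncertainty`` (nm).  Row order is stable
    and preserved by every operation in this package.
    """

    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"localization table is missing mandatory columns: {missing}")
        df = self.df.copy()
        df["frame"] = df["frame"].astype(np.int64)
        df["channel"] = df["channel"].astype(str)
        for col in ("x", "y", "photons"):
            df[col] = df[col].astype(float)
        if "uncertainty" not in df.columns:
            df["uncertainty"] = np.nan
        df = df[list(ALL_COLUMNS)].reset_index(drop=True)
        if (df["frame"] < 0).any():
            raise ValueError("frame indices must be non-negative")
        if not np.isfinite(df[["x", "y"]].to_numpy()).all():
            raise ValueError("x/y coordinates must be finite")
        object.__setattr__(self, "df", df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def xy(self) -> np.ndarray:
        return self.df[["x", "y"]].to_numpy(dtype=float)

    @property
    def frames(self) -> np.ndarray:
        return self.df["frame"].to_numpy()

    def channels(self) -> list[str]:
        return sorted(self.df["channel"].unique())

    def select_channel(self, channel: str) -> "LocalizationTable":
        return LocalizationTable(self.df[self.df["channel"] == str(channel)])

    def with_xy(self, xy: np.ndarray) -> "LocalizationTable":
        """Return a copy with replaced coordinates (all other columns kept)."""
        xy = np.asarray(xy, dtype=float)
        if xy.shape != (len(self), 2):
            raise ValueError("replacement coordinates must match the table shape")
        df = self.df.copy()
        df["x"] = xy[:, 0]
        df["y"] = xy[:, 1]
        return LocalizationTable(df)

    @staticmethod
    def concat(tables: list["LocalizationTable"]) -> "LocalizationTable":
        if not tables:
            raise ValueError("cannot concatenate an empty list of tables")
        return LocalizationTable(pd.concat([t.df for t in tables], ignore_index=True))

    # ------------------------------------------------------------------ I/O

    def write_csv(self, path, dialect: str = "thunderstorm") -> None:
        df = self.df.copy()
        if dialect == "thunderstorm":
            inverse = {v: k for k, v in _THUNDERSTORM_HEADERS.items()}
            df = df.rename(columns=inverse)
            df.to_csv(path, index=False, quoting=2)  # QUOTE_NONNUMERIC, matches the dialect
        elif dialect == "generic":
            df.to_csv(path, index=False)
        else:
            raise ValueError(f"unknown CSV dialect {dialect!r}; use 'thunderstorm' or 'generic'")


def read_localizations(path, dialect: str = "thunderstorm",
                       default_channel: str | None = None) -> LocalizationTable:
    """Read a localization CSV into a :class:`LocalizationTable`.

    Malformed rows (non-numeric values in numeric columns) are rejected with a
    :class:`ValueError` listing the offending file line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in ("thunderstorm", "generic"):
        raise ValueError(f"unknown CSV dialect {dialect!r}; use 'thunderstorm' or 'generic'")
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    df.columns = [c.strip().strip('"') for c in df.columns]
    if dialect == "thunderstorm":
        df = df.rename(columns=_THUNDERSTORM_HEADERS)
    if "channel" not in df.columns and default_channel is not None:
        df["channel"] = str(default_channel)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing mandatory columns: {missing}")
    bad_lines: list[int] = []
    for col in _NUMERIC_COLUMNS:
        if col not in df.columns:
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        # header is file line 1, data starts at line 2
        bad_lines.extend((df.index[bad] + 2).tolist())
        df[col] = converted
    if bad_lines:
        raise ValueError(
            f"{path.name}: malformed rows at file lines {sorted(set(bad_lines))}"
        )
    return LocalizationTable(df)


write_localizations = LocalizationTable.write_csv


@dataclass(frozen=True)
class RenderedImage:
    """A 2D localization histogram (optionally Gaussian-blurred).

    ``image[iy, ix]`` covers x in ``x0 + ix*pixel_nm`` and y likewise; the
    total intensity equals the number of rendered localizations (mass is
    conserved by padding the canvas beyond the blur support).
    """

    image: np.ndarray
    x0: float
    y0: float
    pixel_nm: float

    @property
    def total(self) -> float:
        return float(self.image.sum())


def render_image(table: LocalizationTable, pixel_nm: float = 10.0,
                 blur_sd_nm: float = 0.0, extent=None) -> RenderedImage:
    """Render a table as a 2D histogram at ``pixel_nm`` resolution.

    ``blur_sd_nm`` applies the Gaussian filter the field uses to clean
    super-resolution renders.  ``extent`` is ``(xmin, xmax, ymin, ymax)``; by
    default it is the data bounding box padded by 4 blur sigmas so that the
    blurred mass stays on the canvas.
    """
    if len(table) == 0:
        raise ValueError("cannot render an empty localization table")
    xy = table.xy
    pad = 4.0 * blur_sd_nm + pixel_nm
    if extent is None:
        xmin, ymin = xy.min(axis=0) - pad
        xmax, ymax = xy.max(axis=0) + pad
    else:
        xmin, xmax, ymin, ymax = extent
    nx = max(1, int(np.ceil((xmax - xmin) / pixel_nm)))
    ny = max(1, int(np.ceil((ymax - ymin) / pixel_nm)))
    hist, _, _ = np.histogram2d(
        xy[:, 1], xy[:, 0], bins=[ny, nx],
        range=[[ymin, ymin + ny * pixel_nm], [xmin, xmin + nx * pixel_nm]],
    )
    if blur_sd_nm > 0:
        hist = gaussian_filter(hist, sigma=blur_sd_nm / pixel_nm, mode="constant")
    return RenderedImage(image=hist, x0=float(xmin), y0=float(ymin), pixel_nm=float(pixel_nm))
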