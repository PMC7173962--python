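"""Model/Results objects: the high-level fitting interface.

`AxialRingModel` and `LateralProfileModel` wrap the estimation pipelines in
the style of statistical modelling packages: a model is constructed from a
localization table plus analysis options, ``fit()`` performs the estimation
and returns a results object carrying estimates, dispersions and diagnostics
with ``summary()`` and ``plot()`` methods.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import lateral as _lat
from . import ring as _ring
from .localizations import LocalizationTable
from .synthetic import DEFAULT_LOCALIZATION_SD


class AxialRingModel:
    """Ring-geometry model for one axial-view channel.

    Parameters
    ----------
    table : LocalizationTable
        Input localizations (may be multi-channel).
    channel : str, optional
        Channel to analyse; required when the table has several.
    cluster_radius, min_count :
        Punctum grouping parameters (density-based); the 12 nm default
        resolves adjacent nine-fold blades down to the ODF2 ring scale.
    bin_width : float
        Angular-occupancy bin width in radians (default 10 degrees).
    punctum_level : bool
        Measure radii on punctum centroids (default) or raw localizations.
    """

    def __init__(self, table: LocalizationTable, channel: str | None = None,
                 cluster_radius: float = 12.0, min_count: int = 8,
                 bin_width: float = _ring.DEFAULT_BIN_WIDTH,
                 punctum_level: bool = True):
        if channel is not None:
            table = table.select_channel(channel)
        elif len(table.channels()) > 1:
            raise ValueError(
                f"table has channels {table.channels()}; pass channel="
            )
        self.table = table
        self.channel = channel
        self.cluster_radius = cluster_radius
        self.min_count = min_count
        self.bin_width = bin_width
        self.punctum_level = punctum_level

    def fit(self) -> "AxialRingResults":
        puncta = _ring.cluster_puncta(self.table, radius=self.cluster_radius,
                                      min_count=self.min_count)
        center = _ring.fit_ring_center(puncta if puncta.shape[0] >= 3 else self.table)
        points = puncta if self.punctum_level else self.table.xy
        ringfit = _ring.measure_diameter(points, center=center)
        occupancy = _ring.angular_occupancy(self.table, center,
                                            bin_width=self.bin_width)
        n_puncta, mode9 = _ring.symmetry_score(puncta, center=center)
        return AxialRingResults(model=self, ring=ringfit, occupancy=occupancy,
                                puncta=puncta, n_puncta=n_puncta,
                                mode9_ratio=mode9)


@dataclass
class AxialRingResults:
    model: AxialRingModel
    ring: _ring.RingFit
    occupancy: _ring.AngularOccupancy
    puncta: np.ndarray
    n_puncta: int
    mode9_ratio: float

    def summary(self) -> str:
        r = self.ring
        o = self.occupancy
        lines = [
            "Axial ring fit",
            "=" * 46,
            f"{'channel':<28}{self.model.channel or '-'}",
            f"{'n localizations':<28}{len(self.model.table)}",
            f"{'n puncta':<28}{self.n_puncta}",
            f"{'center x, y [nm]':<28}{r.center[0]:.1f}, {r.center[1]:.1f}",
            f"{'mean diameter [nm]':<28}{r.mean_diameter:.1f}",
            f"{'radius sd [nm]':<28}{r.radius_sd:.1f}",
            f"{'ring completeness':<28}{o.completeness:.3f}",
            f"{'missing fraction':<28}{o.missing_fraction:.3f}",
            f"{'mode-9 power ratio':<28}{self.mode9_ratio:.3f}",
            f"{'fit method':<28}{r.fit_method}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "channel": self.model.channel,
            "ring": self.ring.to_dict(),
            "occupancy": self.occupancy.to_dict(),
            "n_puncta": int(self.n_puncta),
            "mode9_ratio": float(self.mode9_ratio),
        }

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        xy = self.model.table.xy
        ax.scatter(xy[:, 0], xy[:, 1], s=2, alpha=0.3, label="localizations")
        ax.scatter(self.puncta[:, 0], self.puncta[:, 1], s=40, marker="x",
                   color="crimson", label="puncta")
        theta = np.linspace(0, 2 * np.pi, 200)
        r = self.ring.mean_diameter / 2
        ax.plot(self.ring.center[0] + r * np.cos(theta),
                self.ring.center[1] + r * np.sin(theta), "k--", lw=1,
                label="fitted ring")
        ax.set_aspect("equal")
        ax.set_xlabel("x [nm]")
        ax.set_ylabel("y [nm]")
        ax.legend(frameon=False, fontsize=8)
        return ax


class LateralProfileModel:
    """Longitudinal-profiling model for a lateral-view two-color dataset.

    The reference channel defines the origin and (via its rod shape) the
    centriole axis; the target channel is projected on the axis, profiled
    and searched for layers.
    """

    def __init__(self, table: LocalizationTable, reference_channel: str,
                 target_channel: str, distal_marker_channel: str | None = None,
                 distal_direction=None, bin_width: float = 10.0,
                 min_separation: float = 50.0, min_prominence: float = 0.2,
                 kernel_sd: float = DEFAULT_LOCALIZATION_SD):
        self.table = table
        self.reference_channel = reference_channel
        self.target_channel = target_channel
        self.distal_marker_channel = distal_marker_channel
        self.distal_direction = distal_direction
        self.bin_width = bin_width
        self.min_separation = min_separation
        self.min_prominence = min_prominence
        self.kernel_sd = kernel_sd

    def fit(self) -> "LateralProfileResults":
        ref = self.table.select_channel(self.reference_channel)
        marker = (self.table.select_channel(self.distal_marker_channel)
                  if self.distal_marker_channel else None)
        axis = _lat.estimate_axis(ref, distal_marker=marker,
                                  distal_direction=self.distal_direction)
        target = self.table.select_channel(self.target_channel)
        profile = _lat.longitudinal_profile(target, axis, bin_width=self.bin_width)
        layers = _lat.detect_layers(profile, min_separation=self.min_separation,
                                    min_prominence=self.min_prominence,
                                    kernel_sd=self.kernel_sd)
        profile.layers = layers
        return LateralProfileResults(model=self, axis=axis, profile=profile,
                                     layers=layers)


@dataclass
class LateralProfileResults:
    model: LateralProfileModel
    axis: _lat.CentrioleAxis
    profile: _lat.LongitudinalProfile
    layers: list

    def distal_boundary(self, quantile: float = 0.95) -> float:
        return _lat.distal_boundary(self.profile, quantile)

    def summary(self) -> str:
        lines = [
            "Longitudinal layer profile",
            "=" * 56,
            f"{'reference channel':<28}{self.model.reference_channel}",
            f"{'target channel':<28}{self.model.target_channel}",
            f"{'n target localizations':<28}{self.profile.n}",
            f"{'n detected layers':<28}{len(self.layers)}",
        ]
        for i, layer in enumerate(self.layers):
            lines.append(
                f"{'layer %d position [nm]' % i:<28}{layer.position:+.1f}"
                f"   (FWHM {layer.width:.0f} nm)"
            )
        lines.append(f"{'distal 95% boundary [nm]':<28}{self.distal_boundary():+.1f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "reference_channel": self.model.reference_channel,
            "target_channel": self.model.target_channel,
            "axis_origin": [float(v) for v in self.axis.origin],
            "axis_direction": [float(v) for v in self.axis.direction],
            "profile": self.profile.to_dict(),
            "layers": [l.to_dict() for l in self.layers],
            "distal_boundary_95": float(self.distal_boundary()),
        }

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3))
        ax.bar(self.profile.bin_centers, self.profile.density,
               width=self.profile.bin_width, color="0.7")
        for layer in self.layers:
            ax.axvline(layer.position, color="crimson", lw=1, ls="--")
        ax.set_xlabel("longitudinal position [nm] (distal positive)")
        ax.set_ylabel("density [1/nm]")
        return ax
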