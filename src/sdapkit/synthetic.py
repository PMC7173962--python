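"""Synthetic two-channel dSTORM data with known ground truth.

The generator emulates the measured geometry of the mother-centriole appendage
region: ring-shaped protein layers of known radius and longitudinal position
(the distal-appendage protein SCLT1 defines longitudinal zero, proximal is
negative), partial angular occupancy, nine-fold punctate clustering, emitter
blinking (a geometric number of localizations per labelled emitter), isotropic
localization noise, lateral stage drift, a second-order chromatic distortion
of the short-wavelength channel, fiducial beads that emit in every frame, and
straight microtubule-fiber bundles anchored at appendage positions.

Every stochastic entry point takes an explicit seed; identical (model, seed)
pairs produce byte-identical tables.  Internally each model component draws
from its own `numpy` seed-sequence stream so that simulating a channel subset
reproduces exactly the corresponding rows of the full simulation.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from ._utils import rotation_matrix, wrap_angle
from .localizations import LocalizationTable

FIDUCIAL_CHANNEL = "FIDUCIAL"
FIBER_CHANNEL = "ALPHA_TUBULIN"

#: default localization precision (sd, nm): a 20 nm resolution figure treated
#: as a FWHM gives 20 / 2.355 ~= 8.5 nm.
DEFAULT_LOCALIZATION_SD = 8.5


# --------------------------------------------------------------------- types


@dataclass
class ProteinLayerSpec:
    """One ring-shaped protein layer of the ground-truth model.

    ``longitudinal_position`` is signed (reference protein = 0, proximal
    negative).  ``n_clusters = 0`` means a continuous ring; ``9`` gives the
    nine-fold punctate arrangement of appendage blades.  ``occupancy_fraction``
    below 1 removes ``n_gap_arcs`` contiguous random arcs whose total angular
    measure is ``(1 - occupancy_fraction) * 2*pi``.
    """

    protein_name: str
    ring_radius: float
    longitudinal_position: float
    axial_sd: float = 20.0
    radial_sd: float = 10.0
    occupancy_fraction: float = 1.0
    n_clusters: int = 0
    cluster_angular_sd: float = 0.0  # radians
    n_emitters: int = 100
    labeling_efficiency: float = 0.8
    n_gap_arcs: int = 1

    def __post_init__(self):
        if self.ring_radius < 0:
            raise ValueError("ring_radius must be >= 0")
        if not 0.0 <= self.occupancy_fraction <= 1.0:
            raise ValueError("occupancy_fraction must lie in [0, 1]")
        if self.n_clusters < 0 or self.n_emitters < 0:
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.labeling_efficiency <= 1.0:
            raise ValueError("labeling_efficiency must lie in [0, 1]")
        if self.n_gap_arcs < 1 or self.n_gap_arcs > 3:
            raise ValueError("n_gap_arcs must be 1..3")


@dataclass
class DriftSpec:
    """Lateral stage drift.  ``rate_or_step`` is nm/frame per axis."""

    kind: str = "none"  # none | linear | random_walk
    rate_or_step: float = 0.0

    def __post_init__(self):
        if self.kind not in ("none", "linear", "random_walk"):
            raise ValueError(f"unknown drift kind {self.kind!r}")

    def realize(self, n_frames: int, rng: np.random.Generator) -> np.ndarray:
        """Per-frame displacement (n_frames, 2) in nm; frame 0 is (0, 0)."""
        if self.kind == "none" or self.rate_or_step == 0.0:
            return np.zeros((n_frames, 2))
        if self.kind == "linear":
            t = np.arange(n_frames, dtype=float)[:, None]
            return t * self.rate_or_step
        steps = rng.normal(0.0, self.rate_or_step, size=(n_frames, 2))
        steps[0] = 0.0
        return np.cumsum(steps, axis=0)


@dataclass
class ChromaticSpec:
    """Second-order 2D polynomial mapping true coordinates to distorted
    short-wavelength-channel coordinates.

    Coefficient order per axis: ``(1, x, y, x^2, x*y, y^2)``.
    """

    coeffs_x: tuple = (0.0, 1.0, 0.0, 0.0, 0.0, 0.0)
    coeffs_y: tuple = (0.0, 0.0, 1.0, 0.0, 0.0, 0.0)

    def __post_init__(self):
        self.coeffs_x = tuple(float(c) for c in self.coeffs_x)
        self.coeffs_y = tuple(float(c) for c in self.coeffs_y)
        if len(self.coeffs_x) != 6 or len(self.coeffs_y) != 6:
            raise ValueError("chromatic coefficients must have 6 entries per axis")

    @classmethod
    def identity(cls) -> "ChromaticSpec":
        return cls()

    @property
    def is_identity(self) -> bool:
        return (self.coeffs_x == (0.0, 1.0, 0.0, 0.0, 0.0, 0.0)
                and self.coeffs_y == (0.0, 0.0, 1.0, 0.0, 0.0, 0.0))

    def apply(self, xy: np.ndarray) -> np.ndarray:
        feats = quadratic_features(xy)
        return np.column_stack([feats @ self.coeffs_x, feats @ self.coeffs_y])


def quadratic_features(xy: np.ndarray) -> np.ndarray:
    """Design matrix ``[1, x, y, x^2, x*y, y^2]`` for a point set."""
    xy = np.asarray(xy, dtype=float)
    x, y = xy[:, 0], xy[:, 1]
    return np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])


@dataclass
class FiberSpec:
    """Straight microtubule-fiber bundles with one endpoint on an anchor locus.

    In the axial view fibers radiate outward from radius ``anchor_radius``; in
    the lateral view they leave from transverse position ``+-anchor_radius`` at
    longitudinal height ``anchor_longitudinal`` with a slope drawn from
    ``slope_range`` (radians; positive tilts toward the distal end).
    """

    n_fibers: int
    anchor_radius: float
    anchor_longitudinal: float
    length_range: tuple = (500.0, 1500.0)
    angular_range: float = 2.0 * np.pi
    linewidth_sd: float = 12.0
    emitter_spacing: float = 12.0
    orientation_jitter_sd: float = 0.2
    slope_range: tuple = (-0.26, 0.26)

    def __post_init__(self):
        if self.n_fibers < 0:
            raise ValueError("n_fibers must be >= 0")
        if self.length_range[0] <= 0 or self.length_range[1] < self.length_range[0]:
            raise ValueError("length_range must be an increasing positive pair")


@dataclass
class GroundTruthModel:
    """Full generative description of one simulated centriole field."""

    layers: list = field(default_factory=list)
    view: str = "axial"  # axial | lateral
    rotation: float = 0.0
    center: tuple = (0.0, 0.0)
    localization_sd: float = DEFAULT_LOCALIZATION_SD
    mean_locs_per_emitter: float = 5.0
    background_density: float = 1.0  # localizations per um^2 per channel
    n_frames: int = 15000
    drift: DriftSpec = field(default_factory=DriftSpec)
    chromatic: ChromaticSpec = field(default_factory=ChromaticSpec.identity)
    chromatic_channels: tuple = ("SCLT1",)
    fiducials: tuple = ()
    fibers: list = field(default_factory=list)
    focal_depth: float = 400.0
    seed: int | None = None

    def __post_init__(self):
        if self.view not in ("axial", "lateral"):
            raise ValueError(f"unknown view {self.view!r}")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.localization_sd < 0:
            raise ValueError("localization_sd must be >= 0")

    def channels(self) -> list[str]:
        return sorted({layer.protein_name for layer in self.layers})

    # --------------------------------------------------------- serialization

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["center"] = list(self.center)
        d["fiducials"] = [list(f) for f in self.fiducials]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthModel":
        d = dict(d)
        d["layers"] = [ProteinLayerSpec(**ld) for ld in d.get("layers", [])]
        d["drift"] = DriftSpec(**d.get("drift", {}))
        chrom = d.get("chromatic", {})
        d["chromatic"] = ChromaticSpec(**chrom) if isinstance(chrom, dict) else chrom
        d["fibers"] = [FiberSpec(**fd) for fd in d.get("fibers", [])]
        d["center"] = tuple(d.get("center", (0.0, 0.0)))
        d["fiducials"] = tuple(tuple(f) for f in d.get("fiducials", ()))
        d["chromatic_channels"] = tuple(d.get("chromatic_channels", ("SCLT1",)))
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        def _clean(obj):
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        text = yaml.safe_dump(_clean(self.to_dict()), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "GroundTruthModel":
        try:
            text = open(source).read()
        except (OSError, TypeError):
            text = source
        return cls.from_dict(yaml.safe_load(text))


# ------------------------------------------------------------------- presets

_DEG = np.pi / 180.0


def _wild_type_layers() -> list[ProteinLayerSpec]:
    L = ProteinLayerSpec
    nine = dict(n_clusters=9, cluster_angular_sd=5 * _DEG)
    loose = dict(n_clusters=9, cluster_angular_sd=6 * _DEG)
    return [
        L("SCLT1", 200.0, 0.0, axial_sd=15.0, radial_sd=12.0, n_emitters=180, **nine),
        L("ODF2", 100.0, -100.0, axial_sd=20.0, radial_sd=8.0, n_emitters=140, **nine),
        L("ODF2", 100.0, -200.0, axial_sd=20.0, radial_sd=8.0, n_emitters=140, **nine),
        L("CEP128", 125.0, -160.0, axial_sd=20.0, radial_sd=8.0, n_emitters=200, **nine),
        L("CENTRIOLIN", 150.0, -130.0, axial_sd=22.0, radial_sd=10.0, n_emitters=160, **loose),
        L("CEP89", 175.0, -20.0, axial_sd=15.0, radial_sd=10.0, n_emitters=140, **nine),
        L("CEP89", 160.0, -120.0, axial_sd=15.0, radial_sd=10.0, n_emitters=140, **nine),
        L("NINEIN", 300.0, -150.0, axial_sd=40.0, radial_sd=20.0, n_emitters=220, **loose),
        L("NINEIN", 100.0, -500.0, axial_sd=40.0, radial_sd=30.0, n_emitters=160),
        L("CEP170", 300.0, -150.0, axial_sd=40.0, radial_sd=20.0, n_emitters=220, **loose),
        L("CEP170", 100.0, -500.0, axial_sd=40.0, radial_sd=30.0, n_emitters=160),
        L("CNAP1", 100.0, -500.0, axial_sd=30.0, radial_sd=15.0, n_emitters=160),
        L("CP110", 75.0, 40.0, axial_sd=15.0, radial_sd=20.0, n_emitters=150),
    ]


def _gamma_layers(ko: bool) -> list[ProteinLayerSpec]:
    L = ProteinLayerSpec
    if ko:
        # sDAP loss releases the distal confinement: the cylinder spreads
        # toward the DAP level and the sDAP-tip subpopulation disappears.
        return [L("GAMMA_TUBULIN", 200.0, -250.0, axial_sd=120.0, radial_sd=30.0,
                  n_emitters=300)]
    return [
        L("GAMMA_TUBULIN", 200.0, -325.0, axial_sd=100.0, radial_sd=30.0, n_emitters=300),
        L("GAMMA_TUBULIN", 300.0, -160.0, axial_sd=25.0, radial_sd=25.0, n_emitters=30),
    ]


def _preset_wild_type() -> GroundTruthModel:
    return GroundTruthModel(layers=_wild_type_layers())


def _preset_cep128_ko() -> GroundTruthModel:
    L = ProteinLayerSpec
    nine = dict(n_clusters=9, cluster_angular_sd=5 * _DEG)
    layers = [
        L("SCLT1", 200.0, 0.0, axial_sd=15.0, radial_sd=12.0, n_emitters=180, **nine),
        # single thinned ODF2 layer, shifted proximally (larger gap to SCLT1)
        L("ODF2", 100.0, -170.0, axial_sd=12.0, radial_sd=6.0, n_emitters=140, **nine),
        # CEP89 keeps only its DAP layer; the proximal (sDAP) layer is absent
        L("CEP89", 175.0, -20.0, axial_sd=15.0, radial_sd=10.0, n_emitters=140, **nine),
        L("CNAP1", 100.0, -500.0, axial_sd=30.0, radial_sd=15.0, n_emitters=160),
        L("CP110", 75.0, 40.0, axial_sd=15.0, radial_sd=20.0, n_emitters=150),
    ] + _gamma_layers(ko=True)
    return GroundTruthModel(layers=layers)


def _preset_cep83_ko() -> GroundTruthModel:
    L = ProteinLayerSpec
    nine = dict(n_clusters=9, cluster_angular_sd=5 * _DEG)
    loose = dict(n_clusters=9, cluster_angular_sd=6 * _DEG)
    layers = [
        # DAPs are lost (no SCLT1/CEP89 DAP layer); CP110 still caps the
        # distal end and serves as the orientation reference.
        L("CP110", 75.0, 40.0, axial_sd=15.0, radial_sd=20.0, n_emitters=150),
        L("ODF2", 100.0, -200.0, axial_sd=20.0, radial_sd=8.0, n_emitters=140, **nine),
        L("CEP128", 125.0, -160.0, axial_sd=20.0, radial_sd=8.0, n_emitters=200, **nine),
        # ninein relaxes distally, covering the region DAPs used to occupy
        L("NINEIN", 300.0, -100.0, axial_sd=60.0, radial_sd=25.0, n_emitters=220, **loose),
        L("NINEIN", 100.0, -500.0, axial_sd=40.0, radial_sd=30.0, n_emitters=160),
        L("CNAP1", 100.0, -500.0, axial_sd=30.0, radial_sd=15.0, n_emitters=160),
    ]
    return GroundTruthModel(layers=layers)


def _preset_fbs(occupancy: float, cep170_radial_sd: float) -> GroundTruthModel:
    L = ProteinLayerSpec
    layers = [
        L("SCLT1", 200.0, 0.0, axial_sd=15.0, radial_sd=12.0, n_emitters=180,
          n_clusters=9, cluster_angular_sd=5 * _DEG),
        L("CEP128", 125.0, -160.0, axial_sd=20.0, radial_sd=8.0, n_emitters=150,
          occupancy_fraction=occupancy, n_gap_arcs=1),
        L("CEP170", 300.0, -150.0, axial_sd=40.0, radial_sd=cep170_radial_sd,
          n_emitters=150, occupancy_fraction=min(1.0, occupancy + 0.1)),
    ]
    return GroundTruthModel(layers=layers)


def _preset_gamma() -> GroundTruthModel:
    L = ProteinLayerSpec
    layers = [
        L("SCLT1", 200.0, 0.0, axial_sd=15.0, radial_sd=12.0, n_emitters=180,
          n_clusters=9, cluster_angular_sd=5 * _DEG),
        L("CP110", 75.0, 40.0, axial_sd=15.0, radial_sd=20.0, n_emitters=150),
    ] + _gamma_layers(ko=False)
    return GroundTruthModel(layers=layers)


_SDAP_FIBERS = FiberSpec(n_fibers=9, anchor_radius=300.0, anchor_longitudinal=-160.0,
                         slope_range=(-0.26, 0.26))
_DAP_FIBERS = FiberSpec(n_fibers=6, anchor_radius=200.0, anchor_longitudinal=-20.0,
                        slope_range=(-0.09, 0.52))


def _preset_fibers(ko: bool) -> GroundTruthModel:
    L = ProteinLayerSpec
    layers = [
        L("SCLT1", 200.0, 0.0, axial_sd=15.0, radial_sd=12.0, n_emitters=180,
          n_clusters=9, cluster_angular_sd=5 * _DEG),
    ]
    fibers = [_DAP_FIBERS] if ko else [_SDAP_FIBERS, _DAP_FIBERS]
    return GroundTruthModel(layers=layers, fibers=list(fibers))


_PRESETS = {
    "wild_type": _preset_wild_type,
    "CEP128_KO": _preset_cep128_ko,
    "CEP83_KO": _preset_cep83_ko,
    "FBS_plus": lambda: _preset_fbs(occupancy=0.5, cep170_radial_sd=50.0),
    "FBS_minus": lambda: _preset_fbs(occupancy=0.75, cep170_radial_sd=25.0),
    "gamma_tubulin": _preset_gamma,
    "fibers_WT": lambda: _preset_fibers(ko=False),
    "fibers_KO": lambda: _preset_fibers(ko=True),
}


def available_presets() -> list[str]:
    return sorted(_PRESETS)


def build_model_from_paper(preset_name: str, view: str = "axial") -> GroundTruthModel:
    """Return a packaged ground-truth model encoding the measured geometry.

    ``wild_type`` encodes the wild-type appendage architecture (ODF2 ring
    diameter ~200 nm at the centriole wall, ninein/CEP170 at ~600 nm, CEP128
    one compact layer 160 nm proximal to SCLT1, dual ODF2 and CEP89 layers).
    Knockout presets remove or shift layers accordingly.  ``view`` selects the
    simulated projection (``axial`` or ``lateral``).
    """
    if preset_name not in _PRESETS:
        raise ValueError(
            f"unknown preset {preset_name!r}; available presets: {available_presets()}"
        )
    model = _PRESETS[preset_name]()
    model.view = view
    return model


# ------------------------------------------------------------------ sampling


def _draw_gap_arcs(occupancy: float, n_arcs: int, rng: np.random.Generator):
    """Contiguous missing arcs (start, extent) totalling (1-occupancy)*2pi."""
    missing = (1.0 - occupancy) * 2.0 * np.pi
    if missing <= 0:
        return []
    occupied = 2.0 * np.pi - missing
    miss_parts = missing * rng.dirichlet(np.ones(n_arcs))
    occ_parts = occupied * rng.dirichlet(np.ones(n_arcs))
    start = rng.uniform(0.0, 2.0 * np.pi)
    arcs = []
    pos = start
    for m, o in zip(miss_parts, occ_parts):
        arcs.append((wrap_angle(pos), m))
        pos += m + o
    return arcs


def _in_gap(theta: np.ndarray, arcs) -> np.ndarray:
    mask = np.zeros(theta.shape, dtype=bool)
    t = wrap_angle(theta)
    for start, extent in arcs:
        rel = wrap_angle(t - start)
        mask |= rel < extent
    return mask


def _sample_layer(layer: ProteinLayerSpec, model: GroundTruthModel,
                  blade_phase: float, rng: np.random.Generator):
    """Emitter positions (world nm) for one layer, plus its gap arcs."""
    n = layer.n_emitters
    if layer.n_clusters > 0:
        centers = blade_phase + 2.0 * np.pi * np.arange(layer.n_clusters) / layer.n_clusters
        which = rng.integers(0, layer.n_clusters, size=n)
        theta = centers[which] + rng.normal(0.0, layer.cluster_angular_sd, size=n)
    else:
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    arcs = _draw_gap_arcs(layer.occupancy_fraction, layer.n_gap_arcs, rng)
    keep = ~_in_gap(theta, arcs)
    keep &= rng.random(n) < layer.labeling_efficiency
    theta = theta[keep]
    m = theta.size
    r = layer.ring_radius + rng.normal(0.0, layer.radial_sd, size=m)
    z = layer.longitudinal_position + rng.normal(0.0, layer.axial_sd, size=m)
    if model.view == "axial":
        local = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    else:
        # orthographic side projection: transverse chord position + height
        local = np.column_stack([r * np.cos(theta), z])
    world = np.asarray(model.center) + local @ rotation_matrix(model.rotation).T
    return world, arcs


def _blink(rng: np.random.Generator, n_emitters: int, mean_locs: float) -> np.ndarray:
    if mean_locs <= 1.0:
        return np.ones(n_emitters, dtype=int)
    return rng.geometric(1.0 / mean_locs, size=n_emitters)


def _emit_rows(rng, positions, counts, model, channel):
    """Expand emitters into localization rows with blinking + noise + frames."""
    total = int(counts.sum())
    base = np.repeat(positions, counts, axis=0)
    noisy = base + rng.normal(0.0, model.localization_sd, size=(total, 2))
    frames = rng.integers(0, model.n_frames, size=total)
    photons = rng.gamma(2.0, 500.0, size=total)
    return pd.DataFrame({
        "frame": frames,
        "channel": channel,
        "x": noisy[:, 0],
        "y": noisy[:, 1],
        "photons": photons,
        "uncertainty": np.full(total, float(model.localization_sd)),
    })


def _field_halfwidth(model: GroundTruthModel) -> float:
    extents = [abs(model.center[0]), abs(model.center[1])]
    for layer in model.layers:
        extents.append(layer.ring_radius + 4 * layer.radial_sd
                       + abs(layer.longitudinal_position) + 4 * layer.axial_sd)
    for fx, fy in model.fiducials:
        extents.append(abs(fx))
        extents.append(abs(fy))
    return max(extents) + 200.0


def _axial_included(layer: ProteinLayerSpec, model: GroundTruthModel) -> bool:
    """Layers far below the focal plane are invisible in the axial view."""
    if model.view != "axial" or not model.layers:
        return True
    distal_max = max(l.longitudinal_position for l in model.layers)
    return layer.longitudinal_position >= distal_max - model.focal_depth


def simulate_centriole(model: GroundTruthModel, seed: int, channels=None):
    """Simulate one centriole field.

    Returns ``(LocalizationTable, sidecar)`` where the sidecar dict records the
    full model, the realized blade phase, per-layer emitter/localization
    counts and gap arcs, background counts, and the drift trajectory.
    ``channels`` optionally restricts the simulation to a channel subset; the
    rows produced are identical to the corresponding rows of a full run.
    """
    if seed is None:
        raise ValueError("an explicit seed is required")
    phase_rng = np.random.default_rng([int(seed), 0])
    blade_phase = float(phase_rng.uniform(0.0, 2.0 * np.pi))
    drift_rng = np.random.default_rng([int(seed), 4])
    drift = model.drift.realize(model.n_frames, drift_rng)

    wanted = None if channels is None else {str(c) for c in channels}
    parts: list[pd.DataFrame] = []
    layer_info = []
    for li, layer in enumerate(model.layers):
        rng = np.random.default_rng([int(seed), 1, li])
        included = _axial_included(layer, model)
        selected = included and (wanted is None or layer.protein_name in wanted)
        # draw even when skipped so that streams stay aligned per layer index
        positions, arcs = _sample_layer(layer, model, blade_phase, rng)
        counts = _blink(rng, positions.shape[0], model.mean_locs_per_emitter)
        rows = _emit_rows(rng, positions, counts, model, layer.protein_name)
        info = {
            "protein": layer.protein_name,
            "included": bool(included),
            "n_emitters_labeled": int(positions.shape[0]),
            "n_localizations": int(len(rows)) if selected else 0,
            "gap_arcs": [[float(a), float(b)] for a, b in arcs],
        }
        layer_info.append(info)
        if selected:
            parts.append(rows)

    # uniform background, one draw per distinct imaging channel
    half = _field_halfwidth(model)
    area_um2 = (2 * half / 1000.0) ** 2
    background = {}
    for ci, channel in enumerate(model.channels()):
        rng = np.random.default_rng([int(seed), 2, ci])
        n_bg = int(rng.poisson(model.background_density * area_um2))
        xy = rng.uniform(-half, half, size=(n_bg, 2)) + np.asarray(model.center)
        frames = rng.integers(0, model.n_frames, size=n_bg)
        if wanted is None or channel in wanted:
            background[channel] = n_bg
            parts.append(pd.DataFrame({
                "frame": frames, "channel": channel,
                "x": xy[:, 0], "y": xy[:, 1],
                "photons": rng.gamma(2.0, 300.0, size=n_bg),
                "uncertainty": np.full(n_bg, float(model.localization_sd)),
            }))

    # fiducial beads: one localization in every frame
    fid_rng = np.random.default_rng([int(seed), 3])
    n_fid_rows = 0
    for fx, fy in model.fiducials:
        frames = np.arange(model.n_frames)
        pos = (np.array([fx, fy])
               + fid_rng.normal(0.0, model.localization_sd, size=(model.n_frames, 2)))
        if wanted is None or FIDUCIAL_CHANNEL in wanted:
            n_fid_rows += model.n_frames
            parts.append(pd.DataFrame({
                "frame": frames, "channel": FIDUCIAL_CHANNEL,
                "x": pos[:, 0], "y": pos[:, 1],
                "photons": np.full(model.n_frames, 5000.0),
                "uncertainty": np.full(model.n_frames, float(model.localization_sd)),
            }))

    df = (pd.concat(parts, ignore_index=True) if parts
          else pd.DataFrame(columns=["frame", "channel", "x", "y", "photons", "uncertainty"]))

    # optics first (chromatic distortion of the short-wavelength channel),
    # then stage drift added per frame
    if not model.chromatic.is_identity and len(df):
        mask = df["channel"].isin(model.chromatic_channels).to_numpy()
        if mask.any():
            xy = df.loc[mask, ["x", "y"]].to_numpy(dtype=float)
            df.loc[mask, ["x", "y"]] = model.chromatic.apply(xy)
    if len(df):
        disp = drift[df["frame"].to_numpy(dtype=int)]
        df[["x", "y"]] = df[["x", "y"]].to_numpy(dtype=float) + disp

    table = LocalizationTable(df)
    sidecar = {
        "seed": int(seed),
        "model": model.to_dict(),
        "blade_phase": blade_phase,
        "layers": layer_info,
        "background": background,
        "n_fiducial_localizations": n_fid_rows,
        "drift_trajectory": drift.tolist() if model.drift.kind != "none" else None,
    }
    return table, sidecar


def simulate_bead_field(n_beads: int, chromatic: ChromaticSpec, noise_sd: float,
                        seed: int, field_halfwidth: float = 3000.0):
    """Matched calibration-bead coordinates in the two channels.

    Returns ``(long_xy, short_xy)``: true long-wavelength positions and their
    distorted + noisy short-wavelength counterparts.
    """
    if n_beads < 6:
        raise ValueError(
            "at least 6 bead pairs are required to identify the 6-coefficient "
            "second-order chromatic mapping"
        )
    rng = np.random.default_rng(seed)
    long_xy = rng.uniform(-field_halfwidth, field_halfwidth, size=(n_beads, 2))
    short_xy = chromatic.apply(long_xy)
    if noise_sd > 0:
        short_xy = short_xy + rng.normal(0.0, noise_sd, size=short_xy.shape)
    return long_xy, short_xy


def simulate_fibers(spec: FiberSpec, model: GroundTruthModel, seed: int) -> LocalizationTable:
    """Simulate straight fiber bundles anchored on the centriole.

    Fibers are chains of blinking emitters along straight segments whose inner
    endpoint lies on the anchor locus; output rows carry the
    ``ALPHA_TUBULIN`` channel.
    """
    rng = np.random.default_rng([int(seed), 7])
    rows = []
    rot = rotation_matrix(model.rotation)
    for _ in range(spec.n_fibers):
        theta = rng.uniform(0.0, spec.angular_range)
        length = rng.uniform(*spec.length_range)
        if model.view == "axial":
            anchor = spec.anchor_radius * np.array([np.cos(theta), np.sin(theta)])
            direction_angle = theta + rng.normal(0.0, spec.orientation_jitter_sd)
            direction = np.array([np.cos(direction_angle), np.sin(direction_angle)])
        else:
            side = 1.0 if rng.random() < 0.5 else -1.0
            anchor = np.array([side * spec.anchor_radius, spec.anchor_longitudinal])
            slope = rng.uniform(*spec.slope_range)
            direction = np.array([side * np.cos(slope), np.sin(slope)])
        t = np.arange(0.0, length, spec.emitter_spacing)
        perp = np.array([-direction[1], direction[0]])
        emitters = (anchor[None, :] + t[:, None] * direction[None, :]
                    + rng.normal(0.0, spec.linewidth_sd, size=(t.size, 1)) * perp[None, :])
        counts = _blink(rng, t.size, model.mean_locs_per_emitter)
        total = int(counts.sum())
        base = np.repeat(emitters, counts, axis=0)
        noisy = base + rng.normal(0.0, model.localization_sd, size=(total, 2))
        world = np.asarray(model.center) + noisy @ rot.T
        rows.append(pd.DataFrame({
            "frame": rng.integers(0, model.n_frames, size=total),
            "channel": FIBER_CHANNEL,
            "x": world[:, 0], "y": world[:, 1],
            "photons": rng.gamma(2.0, 500.0, size=total),
            "uncertainty": np.full(total, float(model.localization_sd)),
        }))
    if not rows:
        return LocalizationTable(pd.DataFrame(
            columns=["frame", "channel", "x", "y", "photons", "uncertainty"]))
    return LocalizationTable(pd.concat(rows, ignore_index=True))
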