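"""Parameter-recovery benchmarks on the packaged geometry presets.

Each routine simulates centrioles from a preset, runs the corresponding
analysis pipeline from scratch and returns the recovered quantities.  They
back both the acceptance script and the recovery test-suite; problem sizes
follow the study conditions (10 centrioles per condition unless stated).
"""
from __future__ import annotations

import numpy as np

from . import corrections as _corr
from . import fibers as _fib
from . import lateral as _lat
from . import ring as _ring
from . import stats as _stats
from .localizations import LocalizationTable
from .models import LateralProfileModel
from .synthetic import (ChromaticSpec, DriftSpec, build_model_from_paper,
                        simulate_bead_field, simulate_centriole,
                        simulate_fibers)

SDAP_ANNULUS = (250.0, 350.0)


def derive_seeds(base_seed: int, n: int, salt: int = 0) -> list[int]:
    """Deterministic per-replicate seeds below 2**31."""
    return [(int(base_seed) * 1009 + salt * 7919 + k * 104729) % (2 ** 31)
            for k in range(1, n + 1)]


# ------------------------------------------------------------ axial recovery


def axial_diameters(preset: str, protein: str, seeds,
                    punctum_level: bool = True) -> list[float]:
    """Mean ring diameter per simulated centriole for one protein channel.

    Punctum-level path: density clustering -> circle fit on centroids ->
    per-punctum radii.  Localization-level path (``punctum_level=False``)
    fits and measures on raw localizations (used for diffuse clouds such as
    the gamma-tubulin cylinder).
    """
    model = build_model_from_paper(preset, view="axial")
    out = []
    for seed in seeds:
        table, _ = simulate_centriole(model, seed, channels=[protein])
        sub = table.select_channel(protein)
        if punctum_level:
            points = _ring.cluster_puncta(sub)
        else:
            points = sub.xy
        center = _ring.fit_ring_center(points)
        out.append(_ring.measure_diameter(points, center=center).mean_diameter)
    return out


def occupancy_missing_fractions(preset: str, seeds,
                                protein: str = "CEP128") -> list[float]:
    """Recovered missing angular-occupancy fraction per simulated ring."""
    model = build_model_from_paper(preset, view="axial")
    out = []
    for seed in seeds:
        table, _ = simulate_centriole(model, seed, channels=[protein])
        sub = table.select_channel(protein)
        center = _ring.fit_ring_center(sub)
        occ = _ring.angular_occupancy(sub, center)
        out.append(occ.missing_fraction)
    return out


def ninefold_scores(seeds, protein: str = "CEP128") -> list[tuple[int, float]]:
    """(puncta count, mode-9 power ratio) per wild-type simulated ring."""
    model = build_model_from_paper("wild_type", view="axial")
    out = []
    for seed in seeds:
        table, _ = simulate_centriole(model, seed, channels=[protein])
        sub = table.select_channel(protein)
        puncta = _ring.cluster_puncta(sub)
        center = _ring.fit_ring_center(puncta)
        out.append(_ring.symmetry_score(puncta, center=center))
    return out


# ---------------------------------------------------------- lateral recovery

_LATERAL_CHANNELS = ["SCLT1", "CEP128", "ODF2", "NINEIN", "CP110"]


def lateral_layer_recovery(seeds) -> dict:
    """Layer positions relative to SCLT1 from lateral wild-type simulations.

    Returns per-seed lists: CEP128 offset (nm, absolute), distal-ODF2 offset,
    ODF2 layer count, and the separation of the two ninein populations.
    """
    model = build_model_from_paper("wild_type", view="lateral")
    res: dict = {"cep128_offset": [], "odf2_distal_offset": [],
                 "odf2_n_layers": [], "ninein_separation": []}
    for seed in seeds:
        table, _ = simulate_centriole(model, seed, channels=_LATERAL_CHANNELS)

        def _fit(target):
            return LateralProfileModel(table, "SCLT1", target,
                                       distal_marker_channel="CP110").fit()

        cep128 = _fit("CEP128")
        best = max(cep128.layers, key=lambda l: l.prominence)
        res["cep128_offset"].append(abs(best.position))

        odf2 = _fit("ODF2")
        res["odf2_n_layers"].append(len(odf2.layers))
        distal = max(odf2.layers, key=lambda l: l.position)
        res["odf2_distal_offset"].append(abs(distal.position))

        ninein = _fit("NINEIN")
        positions = sorted(l.position for l in ninein.layers)
        res["ninein_separation"].append(positions[-1] - positions[0])
    return res


def gamma_boundary_shift(base_seed: int, n_pairs: int = 100) -> dict:
    """Paired WT-vs-sDAP-KO distal boundaries of the gamma-tubulin cylinder.

    Both conditions are profiled against SCLT1 (CP110 fixes the sign); the
    fraction of pairs where the knockout boundary lies distal to (greater
    than) the wild type quantifies the confinement loss.
    """
    channels = ["SCLT1", "GAMMA_TUBULIN", "CP110"]
    wt_model = build_model_from_paper("gamma_tubulin", view="lateral")
    ko_model = build_model_from_paper("CEP128_KO", view="lateral")
    wt_b, ko_b = [], []
    for seed in derive_seeds(base_seed, n_pairs, salt=5):
        for model, sink in ((wt_model, wt_b), (ko_model, ko_b)):
            table, _ = simulate_centriole(model, seed, channels=channels)
            res = LateralProfileModel(table, "SCLT1", "GAMMA_TUBULIN",
                                      distal_marker_channel="CP110").fit()
            sink.append(res.distal_boundary())
    wt_b = np.asarray(wt_b)
    ko_b = np.asarray(ko_b)
    return {
        "wt_boundaries": wt_b.tolist(),
        "ko_boundaries": ko_b.tolist(),
        "fraction_ko_distal": float(np.mean(ko_b > wt_b)),
    }


def ninein_boundary_shift(base_seed: int, n_pairs: int = 100) -> dict:
    """Paired WT-vs-DAP-KO ninein distal boundaries, referenced to CP110.

    The DAP knockout lacks SCLT1, so both conditions use the distal cap
    marker CP110 as origin and the elongated ninein cloud for the axis
    direction.
    """
    channels = ["CP110", "NINEIN"]
    wt_model = build_model_from_paper("wild_type", view="lateral")
    ko_model = build_model_from_paper("CEP83_KO", view="lateral")
    wt_b, ko_b = [], []
    for seed in derive_seeds(base_seed, n_pairs, salt=6):
        for model, sink in ((wt_model, wt_b), (ko_model, ko_b)):
            table, _ = simulate_centriole(model, seed, channels=channels)
            ref = table.select_channel("CP110")
            tgt = table.select_channel("NINEIN")
            axis = _lat.estimate_axis(ref, target=tgt, reference_is_distal=True)
            profile = _lat.longitudinal_profile(tgt, axis)
            sink.append(_lat.distal_boundary(profile))
    wt_b = np.asarray(wt_b)
    ko_b = np.asarray(ko_b)
    return {
        "fraction_ko_distal": float(np.mean(ko_b > wt_b)),
        "mean_shift": float(np.mean(ko_b - wt_b)),
    }


def ko_layer_flags(seed: int) -> dict:
    """Knockout phenotype flags from lateral simulations.

    CEP128 KO: ODF2 collapses to one layer and the proximal CEP89 layer is
    absent.  CEP83 KO: single ODF2 layer (profiled against CP110).
    """
    ko128 = build_model_from_paper("CEP128_KO", view="lateral")
    table, _ = simulate_centriole(ko128, seed,
                                  channels=["SCLT1", "ODF2", "CEP89", "CP110"])
    odf2 = LateralProfileModel(table, "SCLT1", "ODF2",
                               distal_marker_channel="CP110").fit()
    cep89 = LateralProfileModel(table, "SCLT1", "CEP89",
                                distal_marker_channel="CP110").fit()
    ko83 = build_model_from_paper("CEP83_KO", view="lateral")
    t83, _ = simulate_centriole(ko83, seed, channels=["CP110", "ODF2", "CEP128"])
    ref = t83.select_channel("CP110")
    # orient along the rod-free target stack: CEP128+ODF2 span the sDAP region
    stack = LocalizationTable(t83.df[t83.df["channel"].isin(["ODF2", "CEP128"])])
    axis83 = _lat.estimate_axis(ref, target=stack, reference_is_distal=True)
    prof83 = _lat.longitudinal_profile(t83.select_channel("ODF2"), axis83)
    layers83 = _lat.detect_layers(prof83)
    return {
        "cep128_ko_odf2_n_layers": len(odf2.layers),
        "cep128_ko_cep89_proximal_absent": not any(
            l.position <= -80.0 for l in cep89.layers
        ),
        "cep83_ko_odf2_n_layers": len(layers83),
    }


# ------------------------------------------------------------- corrections


def corrections_fidelity(base_seed: int, n_centrioles: int = 10) -> dict:
    """End-to-end fidelity of the drift + chromatic correction chain.

    Returns the max chromatic-coefficient error from 12 noiseless beads, the
    corrected-fiducial RMS over localization precision, and the Mann-Whitney
    p comparing SCLT1 diameters from corrupted+corrected vs clean
    simulations.
    """
    quad = ChromaticSpec(
        coeffs_x=(5.0, 1.001, 2e-4, 4e-6, -2e-6, 3e-6),
        coeffs_y=(-3.0, -1e-4, 0.999, -3e-6, 2e-6, 5e-6),
    )
    long_xy, short_xy = simulate_bead_field(12, quad, 0.0, seed=base_seed)
    # recover the forward distortion itself (true -> distorted)
    fwd = _corr.fit_chromatic_map(long_xy, short_xy)
    coeff_err = float(max(
        np.abs(fwd.coeffs_x - np.asarray(quad.coeffs_x)).max(),
        np.abs(fwd.coeffs_y - np.asarray(quad.coeffs_y)).max(),
    ))
    # the correction map (distorted -> true) for the pipeline below
    bead_long, bead_short = simulate_bead_field(60, quad, 1.0,
                                                seed=base_seed + 1)
    cmap = _corr.fit_chromatic_map(bead_short, bead_long)

    def _corrupted_model():
        m = build_model_from_paper("wild_type", view="axial")
        m.n_frames = 3000
        m.drift = DriftSpec(kind="linear", rate_or_step=0.08)
        m.chromatic = quad
        m.fiducials = ((-900.0, -800.0), (950.0, -700.0), (-750.0, 900.0))
        return m

    def _clean_model():
        m = build_model_from_paper("wild_type", view="axial")
        m.n_frames = 3000
        return m

    corrupted = _corrupted_model()
    clean = _clean_model()
    channels = ["SCLT1", "FIDUCIAL"]
    rms_ratios, corrected_d, clean_d = [], [], []
    for seed in derive_seeds(base_seed, n_centrioles, salt=7):
        table, _ = simulate_centriole(corrupted, seed, channels=channels)
        tracks = _corr.detect_fiducials(table, n_frames=corrupted.n_frames)
        traj = _corr.estimate_drift(tracks, n_frames=corrupted.n_frames)
        table = _corr.apply_drift(table, traj)
        fid = table.select_channel("FIDUCIAL")
        labels = _corr._cluster_labels(fid.xy, eps=100.0, min_samples=10)
        for lab in np.unique(labels[labels >= 0]):
            pts = fid.xy[labels == lab]
            rms = np.sqrt(np.mean(np.sum((pts - pts.mean(axis=0)) ** 2, axis=1) / 2))
            rms_ratios.append(rms / corrupted.localization_sd)
        table = _corr.apply_chromatic_map(table, cmap, channel="SCLT1")
        sub = table.select_channel("SCLT1")
        puncta = _ring.cluster_puncta(sub)
        corrected_d.append(_ring.measure_diameter(puncta).mean_diameter)

        clean_table, _ = simulate_centriole(clean, seed, channels=["SCLT1"])
        puncta = _ring.cluster_puncta(clean_table.select_channel("SCLT1"))
        clean_d.append(_ring.measure_diameter(puncta).mean_diameter)
    comparison = _stats.compare(corrected_d, clean_d)
    return {
        "chromatic_coeff_max_error": coeff_err,
        "fiducial_rms_over_precision": float(np.max(rms_ratios)),
        "diameter_indistinguishable_p": comparison.p_value,
        "corrected_diameters": corrected_d,
        "clean_diameters": clean_d,
    }


# ------------------------------------------------------------------- fibers


def fiber_rate_experiment(base_seed: int, n_per_group: int = 5) -> dict:
    """One WT-vs-KO fiber-rate experiment (axial view, sDAP annulus)."""
    rates = {}
    for preset, salt in (("fibers_WT", 8), ("fibers_KO", 9)):
        model = build_model_from_paper(preset, view="axial")
        group = []
        for seed in derive_seeds(base_seed, n_per_group, salt=salt):
            table, _ = simulate_centriole(model, seed, channels=["SCLT1"])
            puncta = _ring.cluster_puncta(table.select_channel("SCLT1"))
            center = _ring.fit_ring_center(puncta)
            fib_tables = [simulate_fibers(spec, model, seed + i)
                          for i, spec in enumerate(model.fibers)]
            fib_table = LocalizationTable.concat(fib_tables)
            segments = _fib.detect_fiber_segments(fib_table)
            group.append(_fib.count_per_radian(segments, center, SDAP_ANNULUS))
        rates[preset] = group
    comparison = _stats.compare(rates["fibers_WT"], rates["fibers_KO"])
    return {
        "wt_rates": rates["fibers_WT"],
        "ko_rates": rates["fibers_KO"],
        "p_value": comparison.p_value,
        "wt_greater": float(np.mean(rates["fibers_WT"]))
                      > float(np.mean(rates["fibers_KO"])),
    }


def fiber_rate_power(base_seed: int, n_experiments: int = 40) -> float:
    """Fraction of replicate experiments with WT > KO at p < 0.05."""
    hits = 0
    for seed in derive_seeds(base_seed, n_experiments, salt=10):
        res = fiber_rate_experiment(seed)
        if res["wt_greater"] and res["p_value"] < 0.05:
            hits += 1
    return hits / n_experiments
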