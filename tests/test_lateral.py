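"""Axis estimation, longitudinal profiles, layer detection, composites, ROIs."""
import numpy as np
import pytest

from sdapkit.lateral import (CentrioleAxis, align_and_composite, classify_view,
                             detect_layers, distal_boundary, estimate_axis,
                             longitudinal_profile, profile_from_density,
                             roi_density)
from sdapkit.localizations import LocalizationTable
from sdapkit.models import LateralProfileModel
from sdapkit.synthetic import build_model_from_paper, simulate_centriole

from conftest import make_table, ring_points


def rod_cloud(rng, half_length=200.0, thickness=15.0, n=600):
    """A lateral-view reference rod along x."""
    theta = rng.uniform(0, 2 * np.pi, n)
    x = half_length * np.cos(theta)
    y = rng.normal(0, thickness, n)
    return np.column_stack([x, y])


def test_classify_ring_is_axial(rng):
    pts = ring_points(radius=200.0, n=500) + rng.normal(0, 10, (500, 2))
    assert classify_view(make_table(pts)) == "axial"


def test_classify_rod_is_lateral(rng):
    assert classify_view(make_table(rod_cloud(rng))) == "lateral"


def test_classify_intermediate_is_ambiguous(rng):
    pts = np.column_stack([rng.normal(0, np.sqrt(2.0) * 30, 2000),
                           rng.normal(0, 30, 2000)])
    assert classify_view(make_table(pts)) == "ambiguous"


def test_classify_requires_enough_points():
    with pytest.raises(ValueError, match=">= 50"):
        classify_view(make_table(np.zeros((10, 2))))


def test_axis_signed_positions_invariant_under_rotation(rng):
    ref = rod_cloud(rng)
    target = rng.normal((0.0, -160.0), (60.0, 20.0), (400, 2))
    marker = rng.normal((0.0, 60.0), 10.0, (50, 2))
    axis = estimate_axis(make_table(ref), distal_marker=make_table(marker))
    longi0, _ = axis.project(target)

    ang = np.deg2rad(37.0)
    rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    shift = np.array([123.0, -456.0])
    axis_r = estimate_axis(make_table(ref @ rot.T + shift),
                           distal_marker=make_table(marker @ rot.T + shift))
    longi1, _ = axis_r.project(target @ rot.T + shift)
    assert np.allclose(np.sort(longi0), np.sort(longi1), atol=1e-6)


def test_axis_without_orientation_information_errors(rng):
    with pytest.raises(ValueError, match="unidentifiable"):
        estimate_axis(make_table(rod_cloud(rng)))


def test_profile_mass_conservation(rng):
    ref = rod_cloud(rng)
    axis = estimate_axis(make_table(ref), distal_direction=(0, 1))
    target = rng.normal((0, -150), (50, 40), (777, 2))
    profile = longitudinal_profile(make_table(target), axis)
    assert np.sum(profile.density) * profile.bin_width == pytest.approx(777)


def test_target_equal_to_reference_gives_single_layer_at_zero(rng):
    ref = rod_cloud(rng)
    axis = estimate_axis(make_table(ref), distal_direction=(0, 1))
    profile = longitudinal_profile(make_table(ref), axis)
    layers = detect_layers(profile)
    assert len(layers) == 1
    assert abs(layers[0].position) < 5.0


def two_gaussian_profile(separation, sd, weight=0.5, bin_width=2.0):
    x = np.arange(-400, 400 + bin_width, bin_width)
    d = (weight * np.exp(-0.5 * ((x + separation / 2) / sd) ** 2)
         + (1 - weight) * np.exp(-0.5 * ((x - separation / 2) / sd) ** 2))
    d *= 1000.0 / (d.sum() * bin_width)
    return profile_from_density(x, d, bin_width)


def mixture_mode_oracle(separation, sd, kernel_sd, min_separation=50.0,
                        weight=0.5):
    """Modes of the kernel-inflated two-Gaussian mixture by dense grid scan;
    modes closer than min_separation count once."""
    s = np.hypot(sd, kernel_sd)
    x = np.arange(-400, 400, 0.05)
    d = (weight * np.exp(-0.5 * ((x + separation / 2) / s) ** 2)
         + (1 - weight) * np.exp(-0.5 * ((x - separation / 2) / s) ** 2))
    interior = (d[1:-1] > d[:-2]) & (d[1:-1] >= d[2:])
    modes = x[1:-1][interior]
    merged = []
    for m in modes:
        if merged and m - merged[-1] < min_separation:
            continue
        merged.append(m)
    return merged


@pytest.mark.parametrize("separation,sd", [
    (100.0, 20.0),   # clearly bimodal
    (150.0, 25.0),
    (200.0, 40.0),
    (40.0, 25.0),    # unimodal mixture
    (30.0, 15.0),    # bimodal but below min_separation -> one layer
    (250.0, 30.0),
])
def test_layer_detection_matches_mixture_mode_oracle(separation, sd):
    profile = two_gaussian_profile(separation, sd)
    layers = detect_layers(profile, min_separation=50.0, kernel_sd=8.5)
    oracle = mixture_mode_oracle(separation, sd, kernel_sd=8.5)
    assert len(layers) == len(oracle)
    if len(oracle) == 2:
        positions = sorted(l.position for l in layers)
        assert positions == pytest.approx(oracle, abs=5.0)


def test_single_gaussian_layer_position_and_width():
    profile = two_gaussian_profile(0.0, 30.0)
    layers = detect_layers(profile, kernel_sd=8.5)
    assert len(layers) == 1
    assert layers[0].position == pytest.approx(0.0, abs=2.0)
    expected_fwhm = 2.355 * np.hypot(30.0, 8.5)
    assert layers[0].width == pytest.approx(expected_fwhm, rel=0.15)


def test_composite_of_identical_centrioles_scales_linearly(rng):
    """n noiseless copies at random poses sum to n x the single histogram."""
    # coordinates chosen off the 10 nm bin edges so that the pose round-trip
    # cannot flip a histogram bin at floating-point precision
    rod_x = np.tile(np.linspace(-97.5, 97.5, 20), 3)  # all >= 2.5 nm off bin edges
    ref_lat = np.column_stack([rod_x, np.where(np.arange(60) % 2 == 0, 3.0, -3.0)])
    target = np.column_stack([np.full(200, 47.0), np.full(200, -163.0)])
    target[:100, 0] *= -1
    marker = np.column_stack([np.where(np.arange(60) % 2 == 0, 1.0, -1.0),
                              np.full(60, 43.0)])

    def posed(angle, shift):
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        parts = []
        for xy, ch in ((ref_lat, "SCLT1"), (target, "CEP128"), (marker, "CP110")):
            parts.append(make_table(xy @ rot.T + shift, channel=ch))
        return LocalizationTable.concat(parts)

    single = align_and_composite([posed(0.0, (0, 0))], "SCLT1",
                                 distal_marker_channel="CP110")
    poses = [(0.7, (100, -50)), (2.1, (-300, 211)), (4.0, (5, 5))]
    many = align_and_composite([posed(a, s) for a, s in poses], "SCLT1",
                               distal_marker_channel="CP110")
    for ch in single.channels:
        assert np.array_equal(many.channels[ch], 3 * single.channels[ch])


def test_composite_counts_are_conserved(rng):
    model = build_model_from_paper("wild_type", view="lateral")
    tables = [simulate_centriole(model, s, channels=["SCLT1", "ODF2", "CP110"])[0]
              for s in (11, 12)]
    comp = align_and_composite(tables, "SCLT1", distal_marker_channel="CP110",
                               extent=(-2000, 2000, -2000, 2000))
    assert comp.total == sum(len(t) for t in tables)


def test_composite_layer_positions_match_per_centriole_means():
    model = build_model_from_paper("wild_type", view="lateral")
    tables, per_centriole = [], []
    for seed in range(21, 29):
        table, _ = simulate_centriole(model, seed,
                                      channels=["SCLT1", "ODF2", "CP110"])
        tables.append(table)
        res = LateralProfileModel(table, "SCLT1", "ODF2",
                                  distal_marker_channel="CP110").fit()
        per_centriole.append(sorted(l.position for l in res.layers))
    comp = align_and_composite(tables, "SCLT1", distal_marker_channel="CP110")
    img = comp.channels["ODF2"]
    ymin = comp.extent[2]
    centers = ymin + (np.arange(img.shape[0]) + 0.5) * comp.pixel_nm
    profile = profile_from_density(centers, img.sum(axis=1) / comp.pixel_nm,
                                   comp.pixel_nm)
    comp_layers = sorted(l.position for l in detect_layers(profile))
    means = np.mean(per_centriole, axis=0)
    assert len(comp_layers) == 2
    assert comp_layers == pytest.approx(means, abs=10.0)


def test_roi_density_conservation_and_partition(rng):
    axis = CentrioleAxis(origin=(0.0, 0.0), direction=(0.0, 1.0))
    pts = rng.uniform(-100, 100, (500, 2))
    table = make_table(pts)
    count_all, _ = roi_density(table, axis, (-100, 100.001), (0, 100.001))
    assert count_all == 500
    c1, _ = roi_density(table, axis, (-100, 0), (0, 100.001))
    c2, _ = roi_density(table, axis, (0, 100.001), (0, 100.001))
    assert c1 + c2 == 500


def test_distal_boundary_uniform_closed_form():
    x = np.arange(-400 + 5, -100, 10.0)
    profile = profile_from_density(x, np.full(x.size, 1.0), 10.0)
    assert distal_boundary(profile, 0.95) == pytest.approx(-115.0, abs=1e-9)


def test_distal_boundary_from_projections(rng):
    ref = rod_cloud(rng)
    axis = estimate_axis(make_table(ref), distal_direction=(0, 1))
    target = rng.uniform((-50, -400), (50, -100), (20000, 2))
    profile = longitudinal_profile(make_table(target), axis)
    assert distal_boundary(profile, 0.95) == pytest.approx(-115.0, abs=5.0)
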