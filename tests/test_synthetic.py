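"""Ground-truth generator: determinism, conservation, noise composition,
preset geometry."""
import numpy as np
import pandas as pd
import pytest

from sdapkit.synthetic import (ChromaticSpec, FiberSpec, GroundTruthModel,
                               ProteinLayerSpec, available_presets,
                               build_model_from_paper, quadratic_features,
                               simulate_bead_field, simulate_centriole,
                               simulate_fibers)


def simple_model(**overrides):
    layer = ProteinLayerSpec("RING", ring_radius=100.0, longitudinal_position=0.0,
                             axial_sd=0.0, radial_sd=0.0, n_emitters=200,
                             labeling_efficiency=1.0)
    defaults = dict(layers=[layer], localization_sd=0.0, background_density=0.0,
                    n_frames=100)
    defaults.update(overrides)
    return GroundTruthModel(**defaults)


def test_same_model_and_seed_is_byte_identical():
    model = build_model_from_paper("wild_type")
    t1, s1 = simulate_centriole(model, 42)
    t2, s2 = simulate_centriole(model, 42)
    pd.testing.assert_frame_equal(t1.df, t2.df)
    assert s1 == s2


def test_channel_subset_reproduces_full_simulation_rows():
    model = build_model_from_paper("wild_type")
    full, _ = simulate_centriole(model, 3)
    sub, _ = simulate_centriole(model, 3, channels=["ODF2"])
    expected = full.df[full.df["channel"] == "ODF2"].reset_index(drop=True)
    pd.testing.assert_frame_equal(sub.df, expected)


def test_localization_count_matches_sidecar():
    model = build_model_from_paper("wild_type")
    model.fiducials = ((500.0, 500.0),)
    model.n_frames = 500
    table, sidecar = simulate_centriole(model, 5)
    expected = (sum(l["n_localizations"] for l in sidecar["layers"])
                + sum(sidecar["background"].values())
                + sidecar["n_fiducial_localizations"])
    assert len(table) == expected


def test_noiseless_limit_puts_localizations_on_the_ring():
    table, _ = simulate_centriole(simple_model(), 1)
    radii = np.linalg.norm(table.xy, axis=1)
    assert np.allclose(radii, 100.0, atol=1e-9)


def test_lateral_noiseless_chords_lie_within_radius():
    table, _ = simulate_centriole(simple_model(view="lateral"), 1)
    x, y = table.xy[:, 0], table.xy[:, 1]
    assert np.all(np.abs(x) <= 100.0 + 1e-9)
    assert np.allclose(y, 0.0, atol=1e-9)  # axial_sd = 0


def test_radial_variance_composition():
    """Observed radial scatter^2 = radial_sd^2 + localization_sd^2."""
    layer = ProteinLayerSpec("RING", 300.0, 0.0, axial_sd=0.0, radial_sd=8.0,
                             n_emitters=600, labeling_efficiency=1.0)
    model = GroundTruthModel(layers=[layer], localization_sd=8.5,
                             background_density=0.0, n_frames=1000)
    devs = []
    for seed in range(10):
        table, _ = simulate_centriole(model, seed)
        devs.append(np.linalg.norm(table.xy, axis=1) - 300.0)
    devs = np.concatenate(devs)
    assert devs.size >= 10_000
    expected = np.hypot(8.0, 8.5)
    assert np.std(devs) == pytest.approx(expected, rel=0.05)


def test_occupancy_gap_total_measure():
    layer = ProteinLayerSpec("RING", 100.0, 0.0, occupancy_fraction=0.6,
                             n_gap_arcs=3, n_emitters=50)
    model = GroundTruthModel(layers=[layer], background_density=0.0)
    _, sidecar = simulate_centriole(model, 9)
    arcs = sidecar["layers"][0]["gap_arcs"]
    assert len(arcs) == 3
    assert sum(extent for _, extent in arcs) == pytest.approx(0.4 * 2 * np.pi)


def test_bead_field_identity_no_noise_is_equal():
    long_xy, short_xy = simulate_bead_field(12, ChromaticSpec.identity(), 0.0, 1)
    assert np.array_equal(long_xy, short_xy)


def test_bead_field_displacement_matches_polynomial():
    spec = ChromaticSpec(coeffs_x=(2.0, 1.001, 0.0, 1e-6, 0.0, -1e-6),
                         coeffs_y=(-1.0, 0.0, 0.999, 0.0, 2e-6, 0.0))
    long_xy, short_xy = simulate_bead_field(12, spec, 0.0, 2)
    feats = quadratic_features(long_xy)
    expected = np.column_stack([feats @ spec.coeffs_x, feats @ spec.coeffs_y])
    assert np.allclose(short_xy, expected, atol=1e-12)


def test_bead_field_requires_six_beads():
    with pytest.raises(ValueError, match="6 bead"):
        simulate_bead_field(5, ChromaticSpec.identity(), 0.0, 1)


def test_zero_fibers_gives_empty_table():
    spec = FiberSpec(n_fibers=0, anchor_radius=300.0, anchor_longitudinal=-160.0)
    table = simulate_fibers(spec, simple_model(), 1)
    assert len(table) == 0


def test_fiber_anchor_lies_on_anchor_radius():
    spec = FiberSpec(n_fibers=5, anchor_radius=300.0, anchor_longitudinal=-160.0,
                     linewidth_sd=0.0, orientation_jitter_sd=0.0)
    table = simulate_fibers(spec, simple_model(), 4)
    radii = np.linalg.norm(table.xy, axis=1)
    # purely radial noiseless fibers start exactly at the anchor circle
    assert radii.min() == pytest.approx(300.0, abs=1e-9)


def test_unknown_preset_lists_available():
    with pytest.raises(ValueError) as err:
        build_model_from_paper("nope")
    for name in available_presets():
        assert name in str(err.value)


def test_wild_type_preset_encodes_measured_geometry():
    model = build_model_from_paper("wild_type")
    by_name = {}
    for layer in model.layers:
        by_name.setdefault(layer.protein_name, []).append(layer)
    assert all(l.ring_radius == pytest.approx(100.0) for l in by_name["ODF2"])
    assert len(by_name["ODF2"]) == 2  # dual-layer ODF2
    assert by_name["NINEIN"][0].ring_radius == pytest.approx(300.0)
    assert by_name["CEP128"][0].longitudinal_position == pytest.approx(-160.0)


def test_cep128_ko_preset_has_single_odf2_layer_and_no_proximal_cep89():
    model = build_model_from_paper("CEP128_KO")
    odf2 = [l for l in model.layers if l.protein_name == "ODF2"]
    cep89 = [l for l in model.layers if l.protein_name == "CEP89"]
    assert len(odf2) == 1
    assert all(l.longitudinal_position > -80 for l in cep89)
    assert not any(l.protein_name == "CEP128" for l in model.layers)


def test_model_yaml_round_trip_is_lossless(tmp_path):
    model = build_model_from_paper("FBS_plus")
    model.drift.kind = "linear"
    model.drift.rate_or_step = 0.05
    model.fiducials = ((100.0, -200.0),)
    path = tmp_path / "model.yaml"
    model.to_yaml(path)
    back = GroundTruthModel.from_yaml(path)
    assert back == model


def test_layer_spec_validation():
    with pytest.raises(ValueError):
        ProteinLayerSpec("X", -1.0, 0.0)
    with pytest.raises(ValueError):
        ProteinLayerSpec("X", 1.0, 0.0, occupancy_fraction=1.5)
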