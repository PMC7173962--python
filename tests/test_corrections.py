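"""Drift correction and chromatic registration."""
import numpy as np
import pandas as pd
import pytest

from sdapkit.corrections import (DriftTrajectory, apply_chromatic_map,
                                 apply_drift, detect_fiducials, estimate_drift,
                                 fit_chromatic_map)
from sdapkit.synthetic import (ChromaticSpec, DriftSpec, GroundTruthModel,
                               ProteinLayerSpec, quadratic_features,
                               simulate_bead_field, simulate_centriole)

from conftest import make_table, ring_points


def drift_model(kind="none", rate=0.0, n_frames=1000, loc_sd=0.0,
                fiducials=((800.0, -700.0), (-900.0, 650.0), (700.0, 900.0))):
    layer = ProteinLayerSpec("SCLT1", 200.0, 0.0, axial_sd=0.0, radial_sd=12.0,
                             n_emitters=100)
    return GroundTruthModel(layers=[layer], localization_sd=loc_sd,
                            background_density=0.0, n_frames=n_frames,
                            drift=DriftSpec(kind=kind, rate_or_step=rate),
                            fiducials=tuple(fiducials))


# ----------------------------------------------------------------- fiducials


def test_detect_fiducials_recovers_injected_sites():
    model = drift_model(loc_sd=8.5)
    table, _ = simulate_centriole(model, 1, channels=["FIDUCIAL"])
    tracks = detect_fiducials(table, n_frames=model.n_frames)
    assert len(tracks) == 3
    found = sorted(tuple(t.mean().round(0)) for t in tracks.values())
    injected = sorted(model.fiducials)
    bound = 3 * 8.5 / np.sqrt(model.n_frames)  # standard error of the mean
    for (fx, fy), track in zip(injected, found):
        assert abs(track[0] - fx) < 3 * bound + 1
        assert abs(track[1] - fy) < 3 * bound + 1


def test_structural_localizations_are_not_fiducials():
    # ring emitters appear in a small fraction of frames each
    model = drift_model(fiducials=(), loc_sd=8.5, n_frames=5000)
    table, _ = simulate_centriole(model, 2)
    with pytest.raises(ValueError, match="no persistent fiducial"):
        detect_fiducials(table, n_frames=model.n_frames)


def test_single_noiseless_fiducial_tracks_random_walk_exactly():
    model = drift_model(kind="random_walk", rate=0.5, n_frames=400, loc_sd=0.0,
                        fiducials=((0.0, 0.0),))
    table, sidecar = simulate_centriole(model, 3, channels=["FIDUCIAL"])
    tracks = detect_fiducials(table, n_frames=model.n_frames,
                              max_track_scatter=np.inf)
    traj = estimate_drift(tracks, smoothing_window=1, n_frames=model.n_frames)
    truth = np.asarray(sidecar["drift_trajectory"])
    assert np.allclose(traj.displacement, truth, atol=1e-9)


def test_zero_drift_noiseless_trajectory_is_zero():
    model = drift_model(kind="none", loc_sd=0.0, n_frames=300)
    table, _ = simulate_centriole(model, 1, channels=["FIDUCIAL"])
    tracks = detect_fiducials(table, n_frames=model.n_frames)
    traj = estimate_drift(tracks, n_frames=model.n_frames)
    assert np.allclose(traj.displacement, 0.0)


def test_linear_drift_endpoint_recovery():
    """0.05 nm/frame over 10,000 frames -> 500 nm endpoint displacement."""
    model = drift_model(kind="linear", rate=0.05, n_frames=10_000, loc_sd=8.5)
    table, _ = simulate_centriole(model, 4, channels=["FIDUCIAL"])
    tracks = detect_fiducials(table, n_frames=model.n_frames)
    traj = estimate_drift(tracks, smoothing_window=100, n_frames=model.n_frames)
    bound = 3 * 8.5 / np.sqrt(3 * 100)
    assert traj.displacement[-1, 0] == pytest.approx(500.0, abs=3 * bound)
    assert traj.displacement[-1, 1] == pytest.approx(500.0, abs=3 * bound)


def test_apply_drift_identity_and_inverse(rng):
    table = make_table(rng.normal(0, 100, (200, 2)), frame=rng.integers(0, 50, 200))
    zeros = DriftTrajectory(np.zeros((50, 2)))
    pd.testing.assert_frame_equal(apply_drift(table, zeros).df, table.df)
    disp = np.cumsum(rng.normal(0, 1, (50, 2)), axis=0)
    disp[0] = 0
    traj = DriftTrajectory(disp)
    round_trip = apply_drift(apply_drift(table, traj), traj.negated())
    assert np.allclose(round_trip.xy, table.xy, atol=1e-12)


def test_apply_drift_rejects_uncovered_frames():
    table = make_table([[0.0, 0.0]], frame=99)
    with pytest.raises(ValueError, match="frame"):
        apply_drift(table, DriftTrajectory(np.zeros((50, 2))))


def test_corrected_fiducial_rms_within_precision_bound():
    model = drift_model(kind="linear", rate=0.1, n_frames=3000, loc_sd=8.5)
    table, _ = simulate_centriole(model, 5, channels=["FIDUCIAL"])
    tracks = detect_fiducials(table, n_frames=model.n_frames)
    traj = estimate_drift(tracks, n_frames=model.n_frames)
    corrected = apply_drift(table, traj)
    for fx, fy in model.fiducials:
        near = corrected.xy[np.linalg.norm(table.xy - (fx, fy), axis=1) < 400]
        rms = np.sqrt(np.mean(np.sum((near - near.mean(axis=0)) ** 2, axis=1) / 2))
        assert rms <= 1.1 * 8.5


# ----------------------------------------------------------------- chromatic


QUAD = ChromaticSpec(coeffs_x=(4.0, 1.002, -3e-4, 5e-6, -2e-6, 1e-6),
                     coeffs_y=(-2.0, 2e-4, 0.998, -1e-6, 3e-6, -4e-6))


def test_identity_beads_give_identity_map():
    long_xy, short_xy = simulate_bead_field(12, ChromaticSpec.identity(), 0.0, 1)
    cmap = fit_chromatic_map(short_xy, long_xy)
    assert np.allclose(cmap.coeffs_x, (0, 1, 0, 0, 0, 0), atol=1e-9)
    assert np.allclose(cmap.coeffs_y, (0, 0, 1, 0, 0, 0), atol=1e-9)
    assert cmap.residual_rms < 1e-9


def test_known_quadratic_recovered_to_machine_precision():
    long_xy, short_xy = simulate_bead_field(12, QUAD, 0.0, 2)
    # invert: fit the forward distortion long -> short
    fwd = fit_chromatic_map(long_xy, short_xy)
    assert np.allclose(fwd.coeffs_x, QUAD.coeffs_x, atol=1e-9)
    assert np.allclose(fwd.coeffs_y, QUAD.coeffs_y, atol=1e-9)


def test_noisy_beads_residual_matches_injected_noise():
    long_xy, short_xy = simulate_bead_field(100, QUAD, 2.0, 3)
    cmap = fit_chromatic_map(short_xy, long_xy)
    assert 1.5 < cmap.residual_rms < 2.5
    assert cmap.held_out_rms is not None and cmap.held_out_rms <= 3.0


def test_residual_nonincreasing_in_polynomial_order():
    long_xy, short_xy = simulate_bead_field(60, QUAD, 1.0, 4)
    rms = [fit_chromatic_map(short_xy, long_xy, order=o).residual_rms
           for o in (0, 1, 2)]
    assert rms[0] >= rms[1] >= rms[2]


def test_degenerate_bead_layout_raises():
    x = np.linspace(-100, 100, 10)
    line = np.column_stack([x, 2 * x])  # collinear
    with pytest.raises(ValueError, match="degenerate"):
        fit_chromatic_map(line, line)


def test_apply_chromatic_map_transforms_named_channel_only(rng):
    xy = rng.normal(0, 500, (100, 2))
    df = make_table(xy, channel="561").df
    df.loc[50:, "channel"] = "647"
    table = make_table(xy, channel="561")
    table = table.with_xy(xy)
    table.df["channel"] = df["channel"]
    long_xy, short_xy = simulate_bead_field(40, QUAD, 0.0, 5)
    cmap = fit_chromatic_map(short_xy, long_xy)
    out = apply_chromatic_map(table, cmap, channel="561")
    mask = (table.df["channel"] == "561").to_numpy()
    assert not np.allclose(out.xy[mask], table.xy[mask])
    assert np.array_equal(out.xy[~mask], table.xy[~mask])


def test_end_to_end_registration_recovers_ring_center():
    ring = ring_points(radius=200.0, n=300, center=(150.0, -80.0))
    distorted = QUAD.apply(ring)
    long_xy, short_xy = simulate_bead_field(40, QUAD, 0.0, 6)
    cmap = fit_chromatic_map(short_xy, long_xy)
    corrected = cmap.apply(distorted)
    assert np.linalg.norm(corrected.mean(axis=0) - ring.mean(axis=0)) < 3.0
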