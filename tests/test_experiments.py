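import numpy as np
import pytest
from dataclasses import replace

import usblt as u
from usblt.experiments import run_repeated, run_trial


def test_paint_sphere_at_lattice_node(slab_4851):
    spec = u.SourceSpec(shape="sphere", center=(0, 0, 10.0), radius=1.5)
    x = u.paint_source(slab_4851, spec)
    # brute-force distance check: only the centre node is within 1.5 mm
    inside = [i for i, p in enumerate(slab_4851.nodes)
              if np.linalg.norm(p - [0, 0, 10.0]) <= 1.5]
    assert list(np.flatnonzero(x > 0)) == inside
    assert len(inside) == 1
    assert x.max() == 10.0 and x.min() == 0.0


def test_paint_cylinder_depth_extent(slab_4851):
    spec = u.SourceSpec(center=(0, 0, 5.0), radius=1.5, height=5.0)
    x = u.paint_source(slab_4851, spec)
    painted = slab_4851.nodes[x > 0]
    assert np.all(np.abs(painted[:, 2] - 5.0) <= 2.5)
    assert np.all(painted[:, 0] ** 2 + painted[:, 1] ** 2 <= 1.5**2)


def test_paint_two_disjoint_sources_add(slab_4851):
    s1 = u.SourceSpec(center=(-4, 0, 14.0), radius=1.5, height=5.0)
    s2 = u.SourceSpec(center=(4, 0, 14.0), radius=1.5, height=5.0)
    x1, x2 = u.paint_source(slab_4851, s1), u.paint_source(slab_4851, s2)
    assert not np.any((x1 > 0) & (x2 > 0))
    assert np.array_equal(
        x1 + x2, u.paint_source(slab_4851, s1) + u.paint_source(slab_4851, s2)
    )


def test_paint_source_below_resolution_rejected(slab_4851):
    spec = u.SourceSpec(shape="sphere", center=(1.0, 1.0, 5.0), radius=0.3)
    with pytest.raises(ValueError, match="resolution"):
        u.paint_source(slab_4851, spec)


def test_noise_determinism_and_infinite_snr():
    y = u.MeasurementSet(values=np.linspace(1, 2, 50), wavelengths=(600.0,))
    clean = u.add_noise(y, u.NoiseModel(snr_db=np.inf, seed=0))
    assert np.array_equal(clean.values, y.values)
    n1 = u.add_noise(y, u.NoiseModel(20.0, seed=42))
    n2 = u.add_noise(y, u.NoiseModel(20.0, seed=42))
    n3 = u.add_noise(y, u.NoiseModel(20.0, seed=43))
    assert np.array_equal(n1.values, n2.values)
    assert not np.array_equal(n1.values, n3.values)
    assert n1.provenance["snr_db"] == 20.0 and n1.provenance["seed"] == 42


def test_realized_snr_matches_request():
    y = u.MeasurementSet(values=np.ones(100_000), wavelengths=(600.0,))
    noisy = u.add_noise(y, u.NoiseModel(20.0, seed=5))
    eps = noisy.values - y.values
    realized = 20 * np.log10(1.0 / eps.std())
    assert realized == pytest.approx(20.0, abs=0.1)


def test_global_rms_convention():
    y = u.MeasurementSet(values=np.concatenate([np.full(50_000, 0.1),
                                                np.full(50_000, 10.0)]),
                         wavelengths=(600.0,))
    noisy = u.add_noise(y, u.NoiseModel(20.0, seed=5, convention="global-rms"))
    eps = noisy.values - y.values
    # one global sigma: both halves carry the same absolute noise
    assert eps[:50_000].std() == pytest.approx(eps[50_000:].std(), rel=0.02)


def test_us_depth_conversion():
    # 20 mm gel imaged from the far face, source reported at 15.5 mm
    assert u.pr_depth_from_far_face(15.5, 20.0) == pytest.approx(4.5)
    assert u.pr_depth_from_far_face(0.0, 20.0) == 20.0
    with pytest.raises(ValueError):
        u.pr_depth_from_far_face(25.0, 20.0)


def test_trial_is_deterministic(small_testbed):
    rec1, row1 = run_trial(small_testbed, "us_guided", seed=7)
    rec2, row2 = run_trial(small_testbed, "us_guided", seed=7)
    assert row1 == row2
    assert np.array_equal(rec1.x_hat, rec2.x_hat)


def test_methods_share_noise_per_seed(small_testbed):
    y1 = small_testbed.noisy_data(3).values
    y2 = small_testbed.noisy_data(3).values
    assert np.array_equal(y1, y2)  # any method at seed 3 sees these data


def test_noiseless_recovery_of_painted_intensity(small_testbed):
    """With noiseless data and the guided region containing the source, the
    painted intensity of 10 is recovered within 1%."""
    rec = u.reconstruct(
        "us_guided", small_testbed.jacobian, small_testbed.y0, small_testbed.mesh,
        region=small_testbed.region_for("us_guided", 3.0),
    )
    assert np.allclose(rec.x_hat[small_testbed.troi], 10.0, rtol=0.01)
    off = np.setdiff1d(np.arange(small_testbed.mesh.n_nodes), small_testbed.troi)
    assert np.abs(rec.x_hat[off]).max() <= 0.1


def test_noiseless_trial_beats_noisy_trial(small_testbed):
    rec_clean = u.reconstruct(
        "us_guided", small_testbed.jacobian, small_testbed.y0, small_testbed.mesh,
        region=small_testbed.region_for("us_guided", 3.0),
    )
    mse_clean = u.mean_square_error(rec_clean.x_hat, small_testbed.x_true)
    _, row = run_trial(small_testbed, "us_guided", seed=0)
    assert mse_clean < row["mse"]


def test_run_repeated_single_realization(small_testbed):
    report = run_repeated(small_testbed, methods=("us_guided",), realizations=1)
    s = report.summary().iloc[0]
    assert s["n_trials"] == 1
    assert s["mse_std"] == 0.0


def test_run_repeated_pairing_and_stability(small_testbed):
    r1 = run_repeated(small_testbed, methods=("whole", "us_guided"), realizations=4)
    seeds_by_method = {
        m: list(g["seed"]) for m, g in r1.trials.groupby("method")
    }
    assert seeds_by_method["whole"] == seeds_by_method["us_guided"]
    r2 = run_repeated(small_testbed, methods=("whole", "us_guided"), realizations=4)
    assert r1.trials.equals(r2.trials)


def test_two_source_zero_separation_rejected():
    cfg = u.ExperimentConfig()
    with pytest.raises(ValueError):
        u.two_source_experiment(cfg, [0.0], realizations=1)


def test_guide_position_is_source_centroid(small_testbed):
    assert np.allclose(small_testbed.guide_position(), (0, 0, 5.0))


def test_guide_jitter_is_seeded():
    cfg = u.ExperimentConfig(
        dimensions=(20.0, 20.0, 12.0), spacing=2.0,
        detector_extent=(12.0, 12.0), detector_pitch=3.0,
        sources=(u.SourceSpec(center=(0.0, 0.0, 5.0)),),
        us_jitter_sigma=1.0,
    )
    tb = u.Testbed(cfg)
    g1 = tb.guide_position(seed=1)
    g2 = tb.guide_position(seed=1)
    g3 = tb.guide_position(seed=2)
    assert np.array_equal(g1, g2)
    assert not np.array_equal(g1, g3)
    assert not np.allclose(g1, (0, 0, 5.0))
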