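import numpy as np
import pytest

import usblt as u
from usblt.forward import Jacobian
from usblt.inversion import cscg_solve, select_noi, truncate_jacobian


def _jac(matrix, wavelengths=(600.0,), n_detectors=None):
    matrix = np.asarray(matrix, dtype=float)
    n_det = n_detectors if n_detectors is not None else matrix.shape[0] // len(wavelengths)
    return Jacobian(
        matrix=matrix,
        wavelengths=tuple(wavelengths),
        emission_weights=np.full(len(wavelengths), 1 / len(wavelengths)),
        n_detectors=n_det,
    )


def test_total_sensitivity_column_sums():
    jac = _jac([[1, 2], [3, 4]])
    assert np.array_equal(u.total_sensitivity(jac).s, [4, 6])
    single = _jac([[5, 7, 1]])
    assert np.array_equal(u.total_sensitivity(single).s, [5, 7, 1])
    permuted = _jac([[3, 4], [1, 2]])
    assert np.array_equal(u.total_sensitivity(permuted).s, [4, 6])


def test_dynamic_range():
    assert u.dynamic_range_of(u.SensitivityProfile([0.5, 2, 8])) == pytest.approx(16)
    assert u.dynamic_range_of(u.SensitivityProfile([3, 3, 3])) == pytest.approx(1)
    assert u.dynamic_range_of(u.SensitivityProfile([0, 1, 10])) == pytest.approx(10)
    with pytest.raises(ValueError):
        u.dynamic_range_of(u.SensitivityProfile([0.0, 0.0]))


def test_select_noi_band():
    s = u.SensitivityProfile([1, 2, 4, 8, 16])
    assert list(select_noi(s, reference_node=2, d=2)) == [1, 2, 3]  # values 2,4,8
    assert list(select_noi(s, reference_node=2, d=1)) == [2]
    assert list(select_noi(s, reference_node=2, d=16)) == [0, 1, 2, 3, 4]
    with pytest.raises(ValueError, match="sensitiv"):
        select_noi(u.SensitivityProfile([0.0, 1.0]), 0, 3)
    with pytest.raises(ValueError):
        select_noi(s, 2, 0.5)


def test_select_noi_matches_brute_force():
    rng = np.random.default_rng(11)
    for _ in range(1000):
        n = rng.integers(2, 40)
        s = rng.uniform(0, 10, size=n)
        ref = int(rng.integers(0, n))
        if s[ref] <= 0:
            continue
        d = float(rng.uniform(1.0, 20.0))
        expected = sorted(
            i for i in range(n) if s[ref] / d <= s[i] <= s[ref] * d
        )
        got = list(select_noi(u.SensitivityProfile(s), ref, d))
        assert got == expected
        assert ref in got  # the reference node is always inside its own band


def test_noi_monotone_in_dynamic_range():
    rng = np.random.default_rng(3)
    s = u.SensitivityProfile(rng.uniform(0.01, 10, size=200))
    for ref in (0, 57, 199):
        previous = set()
        for d in (1.0, 1.5, 2.0, 3.0, 10.0, 100.0, 1e4):
            current = set(select_noi(s, ref, d).tolist())
            assert previous <= current
            previous = current


def test_us_guided_region(testbed):
    region = u.us_guided_region(testbed.mesh, testbed.profile, (0, 0, 5.0), 3.0)
    assert region.method_tag == "us_guided"
    assert region.reference_node == u.nearest_node(testbed.mesh, (0, 0, 5.0))
    assert region.reference_node in region.noi
    # the guided region contains every true source node at d = 3
    assert set(testbed.troi) <= set(region.noi.tolist())
    with pytest.raises(ValueError, match="bounding box"):
        u.us_guided_region(testbed.mesh, testbed.profile, (100, 0, 5), 3.0)


def test_truncated_sensitivity_dynamic_range_bounded(testbed):
    d = 3.0
    region = u.us_guided_region(testbed.mesh, testbed.profile, (0, 0, 5.0), d)
    sub, _ = truncate_jacobian(testbed.jacobian, region)
    sub_range = u.dynamic_range_of(u.SensitivityProfile(sub.sum(axis=0)))
    assert sub_range <= d * d * (1 + 1e-12)
    assert sub_range < u.dynamic_range_of(testbed.profile)


def test_large_pr_region(slab_4851):
    all_nodes = u.large_pr_region(slab_4851, (0, 0), 20.0)
    assert all_nodes.n_nodes == slab_4851.n_nodes
    region = u.large_pr_region(slab_4851, (0, 0), 7.5)
    # brute-force coordinate filter
    expected = [
        i for i, p in enumerate(slab_4851.nodes)
        if abs(p[0]) <= 7.5 + 1e-9 and abs(p[1]) <= 7.5 + 1e-9
    ]
    assert list(region.noi) == expected
    # no depth limit: every selected (x, y) column holds all z layers
    nz = 11
    assert region.n_nodes % nz == 0
    xy = {(p[0], p[1]) for p in slab_4851.nodes[region.noi]}
    assert region.n_nodes == len(xy) * nz


def test_truncate_jacobian_identity_and_selection():
    jac = _jac([[1, 2], [3, 4]])
    full, cols = truncate_jacobian(jac, u.PermissibleRegion(noi=[0, 1], method_tag="whole"))
    assert np.array_equal(full, jac.matrix)
    sub, cols = truncate_jacobian(jac, u.PermissibleRegion(noi=[1], method_tag="whole"))
    assert sub.shape == (2, 1) and np.array_equal(sub.ravel(), [2, 4])
    assert list(cols) == [1]
    with pytest.raises(ValueError):
        truncate_jacobian(jac, u.PermissibleRegion(noi=[5], method_tag="whole"))


def test_truncated_solve_equals_zero_constrained_full_solve():
    """Least-squares on the truncated columns, embedded with zeros, equals
    the full-system solve with out-of-region unknowns constrained to zero
    (KKT oracle on a dense tiny instance)."""
    rng = np.random.default_rng(5)
    m, n = 15, 8
    a = rng.uniform(0.1, 1.0, size=(m, n))
    y = rng.uniform(size=m)
    noi = np.array([1, 3, 4])
    x_trunc, *_ = np.linalg.lstsq(a[:, noi], y, rcond=None)
    x_emb = np.zeros(n)
    x_emb[noi] = x_trunc
    # KKT system for min ||Ax-y||^2 s.t. x_out = 0
    out = np.setdiff1d(np.arange(n), noi)
    c = np.zeros((len(out), n))
    c[np.arange(len(out)), out] = 1.0
    kkt = np.block([[a.T @ a, c.T], [c, np.zeros((len(out), len(out)))]])
    rhs = np.concatenate([a.T @ y, np.zeros(len(out))])
    x_kkt = np.linalg.solve(kkt, rhs)[:n]
    assert np.allclose(x_emb, x_kkt, atol=1e-8)


class TestCSCGSolve:
    def test_zero_data_gives_zero_solution(self):
        x, stats = cscg_solve(np.ones((4, 3)), np.zeros(4))
        assert np.all(x == 0)
        assert stats["support_size"] == 0

    def test_recovers_sparse_source_in_overdetermined_system(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0.5, 2.0, size=(10, 4))
        x_true = np.array([0.0, 0.0, 3.5, 0.0])
        y = a @ x_true
        x, _ = cscg_solve(a, y)
        x_pinv = np.linalg.pinv(a) @ y  # dense oracle
        assert np.allclose(x, x_true, rtol=1e-6)
        assert np.allclose(x, x_pinv, atol=1e-6 * np.abs(x_pinv).max())

    def test_homogeneity_under_data_scaling(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0.5, 2.0, size=(12, 6))
        y = a @ np.array([0, 1.0, 0, 0, 2.0, 0])
        x1, _ = cscg_solve(a, y)
        x2, _ = cscg_solve(a, 7.0 * y)
        assert np.allclose(x2, 7.0 * x1, rtol=1e-8)

    def test_nonnegative_output(self, testbed):
        y = testbed.noisy_data(0)
        x, _ = cscg_solve(testbed.jacobian.matrix, y)
        assert x.min() >= 0

    def test_zero_columns_dropped_with_warning(self):
        a = np.array([[1.0, 0.0], [2.0, 0.0]])
        y = np.array([1.0, 2.0])
        with pytest.warns(RuntimeWarning, match="zero columns"):
            x, _ = cscg_solve(a, y)
        assert x[1] == 0

    def test_bitwise_reproducibility(self, testbed):
        y = testbed.noisy_data(3)
        x1, _ = cscg_solve(testbed.jacobian.matrix, y)
        x2, _ = cscg_solve(testbed.jacobian.matrix, y)
        assert np.array_equal(x1, x2)


class TestReconstruct:
    def test_whole_mesh_plumbing(self, small_testbed):
        rec = u.reconstruct("whole", small_testbed.jacobian, small_testbed.y0,
                            small_testbed.mesh)
        assert rec.x_hat.shape == (small_testbed.mesh.n_nodes,)
        assert rec.region.method_tag == "whole"
        assert rec.region.n_nodes == small_testbed.mesh.n_nodes

    def test_guided_zeros_outside_region(self, small_testbed):
        rec = u.reconstruct(
            "us_guided", small_testbed.jacobian, small_testbed.noisy_data(0),
            small_testbed.mesh, us_position=(0, 0, 5.0), d=3.0,
        )
        outside = np.setdiff1d(np.arange(small_testbed.mesh.n_nodes), rec.region.noi)
        assert np.all(rec.x_hat[outside] == 0)
        assert rec.x_hat.min() >= 0

    def test_missing_guide_inputs_raise(self, small_testbed):
        with pytest.raises(ValueError, match="us_guided"):
            u.reconstruct("us_guided", small_testbed.jacobian, small_testbed.y0,
                          small_testbed.mesh)
        with pytest.raises(ValueError, match="large_pr"):
            u.reconstruct("large_pr", small_testbed.jacobian, small_testbed.y0,
                          small_testbed.mesh)
        with pytest.raises(ValueError, match="unknown method"):
            u.reconstruct("magic", small_testbed.jacobian, small_testbed.y0,
                          small_testbed.mesh)
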