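import numpy as np
import pytest

from babydcm.mesh import HeadMesh, build_layered_slab_mesh, build_fixture_array
from babydcm.optics import (
    OpticalCoefficients,
    analytic_semi_infinite_fluence,
    assemble_system,
    channel_sensitivity_matrix,
    compute_sensitivity,
    default_coefficients,
    measurement_amplitude,
    nodes_in_sphere,
    region_sensitivity,
    solve_fluence,
)


@pytest.fixture(scope="module")
def small_system(coarse_mesh, homogeneous_coeffs):
    return assemble_system(coarse_mesh, homogeneous_coeffs, 770.0)


@pytest.fixture(scope="module")
def probe_mesh(homogeneous_coeffs):
    """Moderately resolved slab under the probe (positivity/sensitivity)."""
    mesh = build_layered_slab_mesh((60, 40, 24), (5, 2, 17), 2.5, origin=(-10, -20, 0))
    system = assemble_system(mesh, homogeneous_coeffs, 770.0)
    return mesh, system


class TestAssembly:
    def test_p1_mass_matrix_closed_form(self):
        # one tetrahedron, kappa ~ 0: matrix reduces to the P1 mass matrix
        # mua*V/10 diagonal, mua*V/20 off-diagonal (plus the boundary term,
        # suppressed here by a huge refractive-mismatch factor)
        nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        mesh = HeadMesh(nodes, np.array([[0, 1, 2, 3]]), np.array([1]))
        mua = 0.3
        coeffs = OpticalCoefficients({(1, 770.0): (mua, 1e-12)}, A_boundary=1e12)
        system = assemble_system(mesh, coeffs, 770.0)
        M = system.matrix.toarray()
        V = 1.0 / 6.0
        # remove the (tiny but nonzero) stiffness part: kappa = 1/(3(mua+mus))
        kappa = coeffs.kappa(1, 770.0)
        grads = np.array([[-1, -1, -1], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        K = kappa * V * grads @ grads.T
        Mass = M - K
        expected = mua * V / 20.0 * (np.ones((4, 4)) + np.eye(4))
        assert np.allclose(Mass, expected, rtol=1e-6)

    def test_system_symmetric(self, small_system):
        D = small_system.matrix - small_system.matrix.T
        assert abs(D).max() < 1e-12

    def test_small_system_positive_definite(self, homogeneous_coeffs):
        mesh = build_layered_slab_mesh((20, 20, 20), (5, 2, 13), 10)
        system = assemble_system(mesh, homogeneous_coeffs, 770.0)
        w = np.linalg.eigvalsh(system.matrix.toarray())
        assert w.min() > 0

    def test_missing_tissue_coefficients_named(self, coarse_mesh):
        coeffs = OpticalCoefficients({(1, 770.0): (0.01, 1.0)})
        with pytest.raises(KeyError, match="label 2"):
            assemble_system(coarse_mesh, coeffs, 770.0)


class TestFluence:
    def test_source_power_linearity(self, small_system):
        f1 = solve_fluence(small_system, (20, 20, 0), 1.0)
        f2 = solve_fluence(small_system, (20, 20, 0), 2.0)
        assert np.allclose(f2.node_values, 2 * f1.node_values, rtol=1e-12)

    def test_monotone_lateral_decay(self, small_system, coarse_mesh):
        f = solve_fluence(small_system, (20, 20, 0))
        nid = lambda p: int(np.argmin(np.linalg.norm(coarse_mesh.nodes - p, axis=1)))
        phi_near = f.node_values[nid(np.array([30, 20, 10]))]
        phi_far = f.node_values[nid(np.array([40, 20, 10]))]
        assert 0 < phi_far < phi_near

    def test_interior_positivity(self, probe_mesh):
        # linear FEM lacks a discrete maximum principle, so positivity is
        # asserted up to a vanishing undershoot away from the measurement
        # region and strictly inside it
        mesh, system = probe_mesh
        f = solve_fluence(system, (0, 0, 0))
        d = np.linalg.norm(mesh.nodes - np.array([0.0, 0.0, 0.0]), axis=1)
        assert np.all(f.node_values[d <= 15] > 0)
        assert f.node_values.min() >= -1e-4 * f.node_values.max()


class TestAnalyticOracle:
    def test_decays_to_zero_laterally(self):
        near = analytic_semi_infinite_fluence(5.0, 5.0, 0.01, 1.0)
        far = analytic_semi_infinite_fluence(200.0, 5.0, 0.01, 1.0)
        assert far < near * 1e-6

    def test_vanishes_on_extrapolated_plane(self):
        mua, mus, A = 0.01, 1.0, 2.82
        kappa = 1.0 / (3 * (mua + mus))
        zb = 2 * A * kappa
        val = analytic_semi_infinite_fluence(7.0, -zb, mua, mus, A)
        peak = analytic_semi_infinite_fluence(7.0, 5.0, mua, mus, A)
        assert abs(val) < 1e-12 * abs(peak) + 1e-15

    def test_effective_attenuation_definition(self):
        # mueff = sqrt(mua/kappa) = sqrt(3*mua*(mua+mus))
        mua, mus = 0.01, 1.0
        kappa = 1.0 / (3 * (mua + mus))
        assert np.sqrt(mua / kappa) == pytest.approx(np.sqrt(3 * 0.01 * 1.01))

    def test_source_point_rejected(self):
        with pytest.raises(ValueError, match="source"):
            analytic_semi_infinite_fluence(0.0, 1.0 / 1.0, 0.01, 1.0)


class TestSensitivity:
    @pytest.fixture(scope="class")
    def probe_solution(self, probe_mesh):
        mesh, system = probe_mesh
        array = build_fixture_array()
        fwd = solve_fluence(system, array.sources["S1"])
        adj = solve_fluence(system, array.detectors["D1"])
        amp = measurement_amplitude(system, fwd, array.detectors["D1"])
        return mesh, system, array, fwd, adj, amp

    def test_row_effectively_nonnegative(self, probe_solution):
        mesh, _, _, fwd, adj, amp = probe_solution
        row = compute_sensitivity(fwd, adj, amp, mesh)
        assert row.max() > 0
        assert row.min() >= -1e-8 * row.max()

    def test_source_detector_reciprocity(self, probe_solution):
        mesh, system, array, fwd, adj, amp = probe_solution
        amp_rev = measurement_amplitude(system, adj, array.sources["S1"])
        assert abs(amp - amp_rev) / amp < 1e-8
        row = compute_sensitivity(fwd, adj, amp, mesh)
        row_rev = compute_sensitivity(adj, fwd, amp_rev, mesh)
        assert np.abs(row - row_rev).max() <= 1e-8 * np.abs(row).max()

    def test_rejects_nonpositive_amplitude(self, probe_solution):
        mesh, _, _, fwd, adj, _ = probe_solution
        with pytest.raises(ValueError):
            compute_sensitivity(fwd, adj, 0.0, mesh)


class TestChannelMatrix:
    @pytest.fixture(scope="class")
    def channel_matrix(self, fixture_array):
        mesh = build_layered_slab_mesh(
            (80, 64, 32), (5, 2, 25), 4.0, origin=(-32, -32, 0)
        )
        S = channel_sensitivity_matrix(mesh, fixture_array, default_coefficients())
        return mesh, S

    def test_nine_rows_per_wavelength(self, channel_matrix):
        _, S = channel_matrix
        assert S.S0.shape[:2] == (2, 9)

    def test_adjoint_reuse_solve_count(self, fixture_array, monkeypatch):
        import babydcm.optics as optics

        calls = {"n": 0}
        original = optics.solve_fluence

        def counting(*args, **kwargs):
            calls["n"] += 1
            return original(*args, **kwargs)

        monkeypatch.setattr(optics, "solve_fluence", counting)
        mesh = build_layered_slab_mesh(
            (80, 64, 32), (5, 2, 25), 8.0, origin=(-32, -32, 0)
        )
        optics.channel_sensitivity_matrix(
            mesh, fixture_array, default_coefficients(), wavelengths=[770.0]
        )
        assert calls["n"] == 8  # 4 sources + 4 detectors, not 2 x 9

    def test_scalp_sensitivity_exceeds_depth(self, channel_matrix):
        mesh, S = channel_matrix
        mid = np.array([10.0, 0.0, 0.0])  # channel S1-D1 midpoint
        shallow = nodes_in_sphere(mesh, mid + [0, 0, 4], 4.1, label=1)
        deep = nodes_in_sphere(mesh, mid + [0, 0, 24], 4.1, label=3)
        row = S.S0[0][0]
        assert row[shallow].sum() > row[deep].sum() > 0

    def test_region_condensation(self, channel_matrix):
        mesh, S = channel_matrix
        all_nodes = np.arange(mesh.n_nodes)
        total, names = region_sensitivity(S, {"all": all_nodes})
        assert np.allclose(total[:, :, 0], S.S0.sum(axis=2))
        # additivity over disjoint regions
        r1 = nodes_in_sphere(mesh, (20, 0, 12), 4.0)
        r2 = nodes_in_sphere(mesh, (8, 20, 12), 4.0)
        assert len(set(r1) & set(r2)) == 0
        both, _ = region_sensitivity(S, {"union": np.concatenate([r1, r2])})
        parts, _ = region_sensitivity(S, {"r1": r1, "r2": r2})
        assert np.allclose(both[:, :, 0], parts.sum(axis=2))

    def test_region_under_channel_dominates_its_column(self, channel_matrix):
        mesh, S = channel_matrix
        regions = {
            "under_ch1": nodes_in_sphere(mesh, (10, 0, 12), 4.0),
            "under_ch6": nodes_in_sphere(mesh, (10, 20, 12), 4.0),
        }
        table, names = region_sensitivity(S, regions)
        ch1 = table[0, 0]  # channel S1-D1 row
        assert ch1[names.index("under_ch1")] > ch1[names.index("under_ch6")]

    def test_empty_region_rejected(self, channel_matrix):
        _, S = channel_matrix
        with pytest.raises(ValueError, match="nowhere"):
            region_sensitivity(S, {"nowhere": np.array([], dtype=int)})

    def test_hdf5_round_trip(self, channel_matrix, tmp_path):
        from babydcm.optics import SensitivityMatrix

        _, S = channel_matrix
        path = tmp_path / "sens.h5"
        S.to_hdf5(path)
        back = SensitivityMatrix.from_hdf5(path)
        assert back.wavelengths == S.wavelengths
        assert np.allclose(back.S0, S.S0)
        assert back.channel_names == S.channel_names
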