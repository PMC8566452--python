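"""Membrane force laws: worked values, conservation and symmetry."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cellsqueeze import _kernels
from cellsqueeze.forces import (
    ElasticParams,
    area_volume_forces,
    bending_forces,
    kappa,
    stretching_forces,
    total_elastic_forces,
    viscous_forces,
)
from cellsqueeze.mesh import TriMesh, build_icosphere, compute_rest_state

PARAMS = ElasticParams(1.0, 1.0, 1.0, 1.0, 1.0, 1.0)


class TestKappa:
    def test_worked_values(self):
        assert kappa(1.0) == pytest.approx(1.0, abs=1e-15)
        assert kappa(2.0) == pytest.approx(
            (2**0.5 + 2**-2.5) / (2 + 2**-3.0), rel=1e-15
        )
        assert kappa(2.0) == pytest.approx(0.74870, abs=5e-6)

    def test_compression_value_mirrors_extension(self):
        # direct evaluation: (0.5^0.5 + 0.5^-2.5)/(0.5 + 0.5^-3) — the
        # nonlinearity factor is symmetric under λ → 1/λ
        assert kappa(0.5) == pytest.approx(
            (0.5**0.5 + 0.5**-2.5) / (0.5 + 0.5**-3.0), rel=1e-15
        )
        assert kappa(0.5) == pytest.approx(kappa(2.0), rel=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            kappa(0.0)


class TestStretching:
    def test_rest_gives_zero(self, small_mesh):
        mesh, rest = small_mesh
        f = stretching_forces(mesh, rest, mesh.points, 1.0)
        assert np.abs(f).max() <= 1e-12 * np.abs(rest.edge_lengths).max()

    def test_single_edge_doubled_length(self):
        # a tetrahedron whose edge 0-1 is along x; isolate the law on a
        # 2-node chain via the kernel directly
        pos = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        edges = np.array([[0, 1]])
        out = np.zeros_like(pos)
        _kernels.stretch_forces(pos, edges, np.array([1.0]), 1.0, out)
        np.testing.assert_allclose(out[0], [kappa(2.0) * 1.0, 0, 0], rtol=1e-12)
        np.testing.assert_allclose(out[1], -out[0], rtol=1e-12)

    def test_linear_in_modulus(self, small_mesh, rng):
        mesh, rest = small_mesh
        pos = mesh.points * 1.1
        f1 = stretching_forces(mesh, rest, pos, 1.0)
        f3 = stretching_forces(mesh, rest, pos, 3.0)
        np.testing.assert_allclose(f3, 3.0 * f1, rtol=1e-12, atol=1e-14)
        assert np.abs(stretching_forces(mesh, rest, pos, 0.0)).max() == 0.0

    def test_work_matches_energy_integral(self):
        """Force along a slow edge extension integrates to the closed-form
        work of the neo-Hookean spring (finite-difference oracle)."""
        from scipy.integrate import quad

        L0 = 1.0
        lams = np.linspace(1.0, 1.5, 2001)
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        edges = np.array([[0, 1]])
        forces = []
        for lam in lams:
            p = pos.copy()
            p[1, 0] = lam * L0
            out = np.zeros_like(p)
            _kernels.stretch_forces(p, edges, np.array([L0]), 1.0, out)
            forces.append(out[1, 0])  # force on the moving end
        # trapezoid of measured force vs the direct integral of the law
        work_num = np.trapezoid(forces, lams * L0)
        law = lambda lam: -kappa(lam) * (lam - 1.0)
        work_ref, _ = quad(law, 1.0, 1.5)
        assert work_num == pytest.approx(work_ref, rel=1e-6)


class TestBending:
    def test_rest_gives_zero(self, small_mesh):
        mesh, rest = small_mesh
        f = bending_forces(mesh, rest, mesh.points, 1.0)
        assert np.abs(f).max() < 1e-12

    def test_pair_net_force_is_zero(self, rng):
        # random folded pairs: net bending force over the 4 vertices is 0
        for _ in range(10):
            pts = rng.standard_normal((4, 3))
            edges = np.array([[0, 1]])
            apex = np.array([[2, 3]])
            theta0 = np.array([1.0])
            out = np.zeros_like(pts)
            _kernels.bending_forces(pts, edges, apex, theta0, 1.0, out)
            assert np.linalg.norm(out.sum(axis=0)) < 1e-12 * (
                1e-12 + np.abs(out).max()
            )

    def test_pair_load_magnitude_at_double_angle(self):
        # flat pair (θ = π) with rest angle π/2: |dev| = 1, apex load = k_b
        pts = np.array(
            [[0, 0, 0], [0, 1, 0], [1, 0.5, 0], [-1, 0.5, 0]], dtype=float
        )
        edges = np.array([[0, 1]])
        apex = np.array([[2, 3]])
        out = np.zeros_like(pts)
        _kernels.bending_forces(pts, edges, apex, np.array([np.pi / 2]), 1.0, out)
        dev = (np.pi - np.pi / 2) / (np.pi / 2)
        assert np.linalg.norm(out[2]) == pytest.approx(dev, rel=1e-12)

    def test_restores_rest_angle(self, small_mesh, rng):
        mesh, rest = small_mesh
        pos = mesh.points + 0.05 * rng.standard_normal(mesh.points.shape)
        f = bending_forces(mesh, rest, pos, 1.0)
        th1 = _kernels.dihedral_angles(pos, mesh.edges, mesh.edge_apex)
        th2 = _kernels.dihedral_angles(
            pos + 1e-7 * f, mesh.edges, mesh.edge_apex
        )
        dev1 = np.abs(th1 - rest.dihedrals).sum()
        dev2 = np.abs(th2 - rest.dihedrals).sum()
        assert dev2 < dev1


class TestAreaVolume:
    def test_rest_gives_zero(self, small_mesh):
        mesh, rest = small_mesh
        f = area_volume_forces(mesh, rest, mesh.points, 1.0, 1.0, 1.0)
        assert np.abs(f).max() < 1e-12

    def test_local_area_force_on_scaled_triangle(self):
        """Hand evaluation on a doubled-area equilateral triangle."""
        s = np.sqrt(2.0)  # area scales with s²: doubled
        base = np.array(
            [[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]], dtype=float
        )
        pos = base * s
        faces = np.array([[0, 1, 2]])
        S0 = np.sqrt(3) / 4
        out = np.zeros_like(pos)
        _kernels.area_volume_forces(
            pos, faces, np.array([S0]), 1.0, 1.0, 1.0, 0.0, 0.0, out
        )
        ctr = pos.mean(axis=0)
        tvecs = pos - ctr
        tsq = (tvecs**2).sum()
        dS = 2 * S0 - S0
        for k in range(3):
            expected = -dS / tsq * tvecs[k]
            np.testing.assert_allclose(out[k], expected, rtol=1e-12)
            # points from vertex toward centroid
            assert np.dot(out[k], tvecs[k]) < 0

    def test_inflated_sphere_volume_force_points_inward(self, small_mesh):
        mesh, rest = small_mesh
        pos = mesh.points * 1.05  # inflate: V > V0
        f = area_volume_forces(mesh, rest, pos, 0.0, 0.0, 1.0)
        normals = pos / np.linalg.norm(pos, axis=1, keepdims=True)
        assert np.all((f * normals).sum(axis=1) < 0)


class TestViscous:
    def test_zero_velocity_both_modes(self, small_mesh):
        mesh, _ = small_mesh
        v = np.zeros_like(mesh.points)
        for mode in ("literal", "relative"):
            f = viscous_forces(mesh, mesh.points, v, 1.0, mode)
            assert np.abs(f).max() == 0.0

    def test_rigid_translation_distinguishes_modes(self, small_mesh):
        mesh, _ = small_mesh
        v = np.tile([0.3, -0.1, 0.2], (mesh.n_nodes, 1))
        f_rel = viscous_forces(mesh, mesh.points, v, 1.0, "relative")
        f_lit = viscous_forces(mesh, mesh.points, v, 1.0, "literal")
        assert np.abs(f_rel).max() < 1e-14
        assert np.abs(f_lit).max() > 1e-3  # literal form damps bulk motion

    def test_relative_mode_conserves_momentum(self, small_mesh, rng):
        mesh, _ = small_mesh
        v = rng.standard_normal(mesh.points.shape)
        f = viscous_forces(mesh, mesh.points, v, 2.0, "relative")
        assert np.linalg.norm(f.sum(axis=0)) < 1e-12 * np.abs(f).max()

    def test_unknown_mode_rejected(self, small_mesh):
        mesh, _ = small_mesh
        with pytest.raises(ValueError, match="mode"):
            viscous_forces(mesh, mesh.points, mesh.points, 1.0, "bogus")


class TestElasticAggregate:
    def test_net_force_zero_on_random_configurations(self, small_mesh, rng):
        mesh, rest = small_mesh
        for _ in range(5):
            pos = mesh.points + 0.1 * rng.standard_normal(mesh.points.shape)
            f = total_elastic_forces(mesh, rest, pos, PARAMS)
            assert np.linalg.norm(f.sum(axis=0)) < 1e-9 * np.abs(f).max()

    def test_translation_invariance_and_rotation_covariance(
        self, small_mesh, rng
    ):
        mesh, rest = small_mesh
        pos = mesh.points + 0.05 * rng.standard_normal(mesh.points.shape)
        f0 = total_elastic_forces(mesh, rest, pos, PARAMS)
        f_t = total_elastic_forces(mesh, rest, pos + [10.0, -4.0, 2.0], PARAMS)
        np.testing.assert_allclose(f_t, f0, atol=1e-11)
        R = Rotation.random(random_state=3).as_matrix()
        f_r = total_elastic_forces(mesh, rest, pos @ R.T, PARAMS)
        np.testing.assert_allclose(f_r, f0 @ R.T, atol=1e-11)

    def test_homogeneous_degree_one_in_moduli(self, small_mesh, rng):
        mesh, rest = small_mesh
        pos = mesh.points + 0.05 * rng.standard_normal(mesh.points.shape)
        f1 = total_elastic_forces(mesh, rest, pos, PARAMS)
        f2 = total_elastic_forces(mesh, rest, pos, PARAMS.scaled(2.0))
        np.testing.assert_allclose(f2, 2.0 * f1, rtol=1e-12)
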