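"""Material law, element mechanics, solver and stress recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rootpatch import mechanics as mech
from rootpatch.geometry import build_shell_mesh
from rootpatch.mechanics import _Model


def _mats(E_in=100.0, E_out=100.0, nu=0.2):
    return {"inner": mech.MaterialParams(E_in, nu),
            "outer": mech.MaterialParams(E_out, nu)}


class TestLame:
    @given(E=st.floats(1.0, 1e4), nu=st.floats(0.0, 0.49))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_round_trip(self, E, nu):
        lam, mu = mech.lame_from_engineering(E, nu)
        assert mu * (2 * mu + 3 * lam) / (lam + mu) == pytest.approx(E, rel=1e-12)
        if lam > 0:
            assert lam / (2 * (lam + mu)) == pytest.approx(nu, rel=1e-10)

    def test_reference_values(self):
        lam, mu = mech.lame_from_engineering(100.0, 0.2)
        assert lam == pytest.approx(27.7778, rel=1e-4)
        assert mu == pytest.approx(41.6667, rel=1e-4)
        for E in (70.0, 130.0):
            l2, m2 = mech.lame_from_engineering(E, 0.2)
            assert l2 > 0 and m2 > 0

    def test_zero_poisson(self):
        lam, mu = mech.lame_from_engineering(80.0, 0.0)
        assert lam == 0.0
        assert mu == 40.0

    def test_incompressible_rejected(self):
        with pytest.raises(mech.IncompressibilityError):
            mech.lame_from_engineering(100.0, 0.5)


class TestSvkStress:
    def test_zero_strain(self):
        S = mech.svk_stress(np.zeros((2, 2)), mech.MaterialParams(100, 0.2))
        assert np.allclose(S, 0.0)

    def test_uniaxial_plane_stress_limit(self):
        """S11/ε approaches Young's modulus for small uniaxial strain."""
        m = mech.MaterialParams(100.0, 0.2)
        eps = 1e-9
        # plane-stress uniaxial with free lateral strain: complement the
        # lateral contraction implied by the 2D law
        lam_ps, mu = m.lam_plane_stress, m.mu
        e22 = -lam_ps / (lam_ps + 2 * mu) * eps
        S = mech.svk_stress(np.diag([eps, e22]), m, mode="plane_stress")
        assert S[0, 0] / eps == pytest.approx(100.0, rel=1e-6)
        assert S[1, 1] == pytest.approx(0.0, abs=1e-12)

    def test_equibiaxial_3d_value(self):
        """λ tr(E) I + 2μE at E = diag(0.01, 0.01) with λ=27.78, μ=41.67."""
        m = mech.MaterialParams(100.0, 0.2)
        S = mech.svk_stress(np.diag([0.01, 0.01]), m, mode="3D")
        expected = m.lam * 0.02 + 2 * m.mu * 0.01
        assert expected == pytest.approx(1.3889, rel=1e-4)
        assert np.allclose(S, np.diag([expected, expected]))

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            mech.svk_stress(np.array([[0, 1e-3], [0, 0]]),
                            mech.MaterialParams(10, 0.1))


class TestLoads:
    def test_effective_load_subtracts_atmosphere(self):
        lf = mech.LoadField(0.2, 0.4)
        assert lf.effective("outer") == pytest.approx(0.2 - 0.101325)
        assert lf.effective("inner") == pytest.approx(0.4 - 0.101325)

    def test_negative_effective_load_rejected(self):
        with pytest.raises(ValueError):
            mech.LoadField(0.05, 0.2).effective("outer")


class TestAssembly:
    def test_internal_force_is_energy_gradient(self, tiny_mesh, rng):
        """Finite-difference check of ∂U/∂d against the assembled force."""
        model = _Model(tiny_mesh, _mats(), mech.LoadField(0.2, 0.2))
        d = np.zeros(model.ndof)
        d[model.free] = 0.05 * rng.standard_normal(model.free.size)
        f, _ = model.internal_force(d, want_tangent=False)
        eps = 1e-6
        idx = rng.choice(model.free, size=20, replace=False)
        for i in idx:
            dp, dm = d.copy(), d.copy()
            dp[i] += eps
            dm[i] -= eps
            fd = (model.total_energy(dp) - model.total_energy(dm)) / (2 * eps)
            assert fd == pytest.approx(f[i], rel=1e-4, abs=1e-10)

    def test_tangent_matches_force_differential(self, tiny_mesh, rng):
        model = _Model(tiny_mesh, _mats(), mech.LoadField(0.2, 0.2))
        d = np.zeros(model.ndof)
        d[model.free] = 0.02 * rng.standard_normal(model.free.size)
        f0, K = model.internal_force(d)
        v = np.zeros(model.ndof)
        v[model.free] = rng.standard_normal(model.free.size)
        eps = 1e-7
        f1, _ = model.internal_force(d + eps * v, want_tangent=False)
        assert np.allclose((f1 - f0) / eps, K @ v, atol=1e-4 * np.abs(K @ v).max())

    def test_follower_load_totals_vector_area(self, tiny_mesh, rng):
        """Total follower force equals p times the surface vector area,
        which is fixed by the clamped boundary regardless of deformation."""
        lf = mech.LoadField(0.2, 0.2)
        model = _Model(tiny_mesh, _mats(), lf)
        d = np.zeros(model.ndof)
        d[model.free] = 0.3 * rng.standard_normal(model.free.size)
        f, _ = model.external_force_tangent(d, want_tangent=False)
        total = f.reshape(-1, 5)[:, :3].sum(axis=0)
        p = lf.effective("outer")
        assert total == pytest.approx([0.0, 0.0, p * 400.0], abs=1e-9 * p * 400)


class TestEquilibrium:
    def test_zero_load_zero_response(self, tiny_mesh):
        lf = mech.LoadField(mech.ATMOSPHERE_MPA, mech.ATMOSPHERE_MPA)
        st_ = mech.solve_equilibrium(tiny_mesh, _mats(), lf)
        assert np.allclose(st_.displacements, 0.0)
        assert np.allclose(st_.sigma, 0.0)

    def test_linear_plate_limit(self):
        """At 1% of the working load the deflection matches the clamped
        Kirchhoff plate series solution w = 0.00126 q a⁴ / D within 5%."""
        mesh = build_shell_mesh(20, 0.5, (10, 10), 2.0, 40)
        q = 0.01 * (0.2 - mech.ATMOSPHERE_MPA)
        lf = mech.LoadField(q + mech.ATMOSPHERE_MPA, q + mech.ATMOSPHERE_MPA)
        st_ = mech.solve_equilibrium(mesh, _mats(), lf,
                                     mech.SolverOptions(n_load_steps=2))
        D = 100 * 0.5**3 / (12 * (1 - 0.2**2))
        w_series = 0.00126 * q * 20**4 / D
        assert st_.displacements[:, 2].max() == pytest.approx(w_series, rel=0.05)

    def test_full_load_symmetry_and_convergence(self, baseline_state):
        w = baseline_state.displacements[:, 2]
        assert baseline_state.load_fraction == 1.0
        n = int(np.sqrt(w.size))
        W = w.reshape(n, n)
        assert np.abs(W - W[::-1]).max() < 1e-8
        assert np.abs(W - W.T).max() < 1e-8
        # deflection peaks at the centre
        assert W[n // 2, n // 2] == pytest.approx(w.max())

    def test_mesh_convergence_of_deflection(self, baseline_state):
        """Quadrupling the element count changes max deflection < 2%."""
        mesh = build_shell_mesh(20, 0.5, (10, 10), 2.0, 20)
        st_ = mech.solve_equilibrium(mesh, _mats(), mech.LoadField(0.2, 0.2))
        w_coarse = st_.displacements[:, 2].max()
        w_fine = baseline_state.displacements[:, 2].max()
        assert abs(w_fine - w_coarse) / w_fine < 0.02

    def test_mixed_quad_tri_mesh_solves(self):
        """The conforming (circle-split) mesh with triangles reaches the
        same deflection scale as the pure quad grid."""
        mesh = build_shell_mesh(20, 0.5, (10, 10), 2.0, 16, conform=True)
        assert len(mesh.tris) > 0
        st_ = mech.solve_equilibrium(mesh, _mats(70, 100),
                                     mech.LoadField(0.2, 0.2))
        assert st_.load_fraction == 1.0
        assert st_.displacements[:, 2].max() == pytest.approx(2.0, rel=0.05)
        sf = mech.cauchy_and_principal(st_)
        assert np.isfinite(sf.sigma_1).all()

    def test_objectivity_of_stress_measures(self, tiny_mesh):
        """A rigid rotation of the deformed configuration leaves S unchanged
        and rotates the Cauchy tensor."""
        st_ = mech.solve_equilibrium(tiny_mesh, _mats(), mech.LoadField(0.2, 0.2))
        model = _Model(tiny_mesh, _mats(), mech.LoadField(0.2, 0.2))
        d = np.zeros(model.ndof)
        d5 = d.reshape(-1, 5)
        d5[:, :3] = st_.displacements
        _, _, S0, sig0, _ = model.stresses(d)

        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        x_rot = (tiny_mesh.nodes + st_.displacements) @ R.T
        d5[:, :3] = x_rot - tiny_mesh.nodes
        _, _, S1, sig1, _ = model.stresses(d)
        assert np.allclose(S1, S0, atol=1e-8)
        assert np.allclose(sig1, np.einsum("ij,ejk,lk->eil", R, sig0, R),
                           atol=1e-8)


class TestPrincipalStress:
    def test_uniaxial_identity_map(self, tiny_mesh):
        state = mech.KinematicState(
            displacements=np.zeros((1, 3)), rotations=np.zeros((1, 2)),
            F=np.array([np.eye(3)[:, :2]]),
            E=np.zeros((1, 2, 2)), S=np.array([np.diag([3.0, 0.0])]),
            sigma=np.array([np.diag([3.0, 0.0, 0.0])]), J=np.ones(1),
            mesh=tiny_mesh)
        sf = mech.cauchy_and_principal(state)
        assert sf.sigma_1[0] == pytest.approx(3.0)
        assert abs(sf.dir_1[0] @ np.array([1, 0, 0])) == pytest.approx(1.0)

    def test_isotropic_rotated(self, tiny_mesh, rng):
        th = 0.3
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        F = R @ np.eye(3)[:, :2]
        p = 2.5
        sigma = R @ np.diag([p, p, 0.0]) @ R.T
        state = mech.KinematicState(
            displacements=np.zeros((1, 3)), rotations=np.zeros((1, 2)),
            F=np.array([F]), E=np.zeros((1, 2, 2)),
            S=np.array([np.diag([p, p])]), sigma=np.array([sigma]),
            J=np.ones(1), mesh=tiny_mesh)
        sf = mech.cauchy_and_principal(state)
        assert sf.sigma_1[0] == pytest.approx(p)
        assert sf.sigma_2[0] == pytest.approx(p)
        assert sf.dir_1[0] @ sf.dir_2[0] == pytest.approx(0.0, abs=1e-12)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_invariants_match_dense_algebra(self, tiny_mesh, seed):
        rng = np.random.default_rng(seed)
        Ssym = rng.standard_normal((2, 2))
        Ssym = 0.5 * (Ssym + Ssym.T)
        F = np.eye(3)[:, :2] + 0.1 * rng.standard_normal((3, 2))
        J = np.linalg.norm(np.cross(F[:, 0], F[:, 1]))
        sigma = F @ Ssym @ F.T / J
        state = mech.KinematicState(
            displacements=np.zeros((1, 3)), rotations=np.zeros((1, 2)),
            F=np.array([F]), E=np.zeros((1, 2, 2)), S=np.array([Ssym]),
            sigma=np.array([sigma]), J=np.array([J]), mesh=tiny_mesh)
        sf = mech.cauchy_and_principal(state)
        # trace and (in-plane) determinant preserved by the eigensolve
        assert sf.sigma_1[0] + sf.sigma_2[0] == pytest.approx(
            np.trace(sigma), abs=1e-8)
        evals = np.linalg.eigvalsh(sigma)
        dense = sorted(evals, key=abs)[1:]          # drop the ~0 normal mode
        assert sorted([sf.sigma_1[0], sf.sigma_2[0]]) == pytest.approx(
            sorted(dense), abs=1e-8)
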