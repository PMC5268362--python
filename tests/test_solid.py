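import numpy as np
import pytest

from mechangio import generate_cube_mesh
from mechangio.params import (GrowthTriplet, MaterialParams, SolidParams,
                              MMHG_PER_KPA)
from mechangio.solid import (SolidSolver, cauchy_stress, elastic_stress,
                             growth_tensor, growth_volume_strain,
                             hydrostatic_pressure_from_stress, pk2_stress,
                             strain_energy, traction_direction)

TRIPLET = GrowthTriplet(2.0, 3.0, 1.5)


class TestGrowthLaw:
    def test_zero_oxygen_zero_strain(self):
        assert growth_volume_strain(0.0, TRIPLET) == pytest.approx(0.0)

    def test_saturation_limit(self):
        a, b = TRIPLET.alpha, TRIPLET.beta
        limit = a * (1.0 - np.exp(-b))
        assert growth_volume_strain(50.0, TRIPLET) == pytest.approx(
            limit, rel=1e-10)

    def test_monotone_in_oxygen(self):
        xi = np.linspace(0.0, 3.0, 200)
        th = growth_volume_strain(xi, TRIPLET)
        assert np.all(np.diff(th) >= 0)


class TestGrowthTensor:
    def test_identity_without_growth(self):
        Fg = growth_tensor(0.0, 0.0, 0.0, np.zeros(3), np.zeros(3))
        assert np.allclose(Fg, np.eye(3))

    def test_isotropic_growth_determinant(self):
        theta = 0.5
        lam = np.sqrt(2 * theta + 1)
        Fg = growth_tensor(theta, theta, theta, np.zeros(3), np.zeros(3))
        assert np.allclose(Fg, lam * np.eye(3))
        assert np.isclose(np.linalg.det(Fg), lam ** 3)

    def test_directional_term_along_unit_x(self):
        # λ_g-ξ = 1.2 along x, λ_g = 1.1 elsewhere
        th = (1.1 ** 2 - 1) / 2
        th_o = (1.2 ** 2 - 1) / 2
        Fg = growth_tensor(th, th_o, th, np.array([1.0, 0, 0]),
                           np.zeros(3))
        assert np.allclose(Fg, np.diag([1.2, 1.1, 1.1]), atol=1e-4)

    def test_gradient_magnitude_irrelevant_above_noise_floor(self):
        th = 0.3
        g1 = growth_tensor(th, 0.6, th, np.array([2.0, 0, 0]), np.zeros(3))
        g2 = growth_tensor(th, 0.6, th, np.array([0.5, 0, 0]),
                           np.zeros(3))
        assert np.allclose(g1, g2, atol=1e-3)

    def test_noise_scale_gradient_drops_directional_term(self):
        th = 0.3
        lam = np.sqrt(2 * th + 1)
        g = growth_tensor(th, 0.9, th, np.array([1e-6, 0, 0]), np.zeros(3))
        assert np.allclose(g, lam * np.eye(3), atol=1e-6)


class TestConstitutive:
    MAT = MaterialParams(c10=1.0, c20=0.2, c01=0.5, c02=0.1, c11=0.15,
                         kappa=20.0)

    def _random_Ce(self, rng, n=20):
        A = rng.normal(size=(n, 3, 3)) * 0.15
        F = np.eye(3) + A
        return np.swapaxes(F, -1, -2) @ F

    def test_stress_free_at_identity(self):
        S = pk2_stress(np.eye(3), 1.0, self.MAT)
        assert np.allclose(S, 0.0, atol=1e-12)

    def test_pure_growth_gives_zero_stress(self):
        Fg = 1.3 * np.eye(3)
        S = elastic_stress(Fg, Fg, 1.0, self.MAT)
        assert np.allclose(S, 0.0, atol=1e-10)

    def test_isochoric_stress_linear_in_integrity(self):
        rng = np.random.default_rng(0)
        Ce = self._random_Ce(rng)
        mat = MaterialParams(c10=1.0, c01=0.5, kappa=0.0)  # isochoric only
        S1 = pk2_stress(Ce, 1.0, mat)
        S_half = pk2_stress(Ce, 0.5, mat)
        assert np.allclose(S_half, 0.5 * S1, atol=1e-12)

    def test_stress_matches_energy_finite_difference(self):
        """S = 2∂W̄/∂C within 1e-6 relative against central differences on
        random elastic states."""
        rng = np.random.default_rng(7)
        Ce = self._random_Ce(rng, n=10)
        S = pk2_stress(Ce, 0.8, self.MAT)
        h = 1e-6
        S_fd = np.zeros_like(S)
        for i in range(3):
            for j in range(3):
                dC = np.zeros((3, 3))
                dC[i, j] += 0.5 * h
                dC[j, i] += 0.5 * h
                Wp = strain_energy(Ce + dC, 0.8, self.MAT)
                Wm = strain_energy(Ce - dC, 0.8, self.MAT)
                S_fd[:, i, j] = 2.0 * (Wp - Wm) / (2.0 * h)
        scale = np.abs(S).max()
        assert np.abs(S - S_fd).max() < 1e-5 * scale

    def test_small_strain_uniaxial_stiffness(self):
        """Nearly-incompressible uniaxial response ≈ 6(c10+c01) verified
        against the numeric stress from the energy."""
        mat = MaterialParams(c10=1.0, c01=0.5, kappa=3000.0)
        eps = 1e-4
        # incompressible uniaxial: λ, 1/√λ, 1/√λ
        lam = 1.0 + eps
        F = np.diag([lam, lam ** -0.5, lam ** -0.5])
        S = pk2_stress(F.T @ F, 1.0, mat)
        sigma = F @ S @ F.T / np.linalg.det(F)
        # remove residual hydrostatic part (finite κ)
        dev = sigma - np.trace(sigma) / 3 * np.eye(3)
        E_mod = (dev[0, 0] - dev[1, 1]) / eps
        assert E_mod == pytest.approx(6.0 * (mat.c10 + mat.c01), rel=0.01)


class TestTractionDirection:
    def test_diagonal_eigenproblem(self):
        S = np.diag([-3.0, -1.0, 2.0])
        t = traction_direction(S, np.array([1.0, 0, 0]))
        assert np.allclose(np.abs(t), [1, 0, 0], atol=1e-12)

    def test_sign_never_opposes_previous_direction(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            A = rng.normal(size=(3, 3))
            S = A + A.T
            prev = rng.normal(size=3)
            prev /= np.linalg.norm(prev)
            t = traction_direction(S, prev)
            assert np.dot(-t, prev) >= -1e-12

    def test_isotropic_stress_falls_back_to_previous(self):
        prev = np.array([0.0, 1.0, 0.0])
        t = traction_direction(2.5 * np.eye(3), prev)
        assert np.allclose(t, -prev)

    def test_eigen_residual(self):
        rng = np.random.default_rng(11)
        A = rng.normal(size=(40, 3, 3))
        S = A + np.swapaxes(A, -1, -2)
        prev = rng.normal(size=(40, 3))
        t = traction_direction(S, prev)
        lam = np.einsum("kij,ki,kj->k", S, t, t)
        resid = np.einsum("kij,kj->ki", S, t) - lam[:, None] * t
        assert np.abs(resid).max() < 1e-10
        w = np.linalg.eigvalsh(S)
        assert np.allclose(lam, w[:, 0], atol=1e-10)


class TestHydrostaticPressure:
    def test_compression_positive(self):
        S = -4.0 * np.eye(3)
        assert hydrostatic_pressure_from_stress(S) == pytest.approx(4.0)

    def test_zero_for_zero_and_shear(self):
        assert hydrostatic_pressure_from_stress(np.zeros((3, 3))) == 0.0
        shear = np.array([[0, 1.0, 0], [1.0, 0, 0], [0, 0, 0]])
        assert hydrostatic_pressure_from_stress(shear) == 0.0


@pytest.fixture(scope="module")
def unit_solver():
    mesh = generate_cube_mesh(1.0, 4, 0.2)
    return mesh, SolidSolver(mesh, SolidParams())


class TestEquilibrium:
    def test_no_growth_no_displacement(self, unit_solver):
        mesh, solver = unit_solver
        nel = mesh.n_elems
        Fg = np.tile(np.eye(3), (nel, 8, 1, 1))
        st = solver.solve(Fg, np.ones((nel, 8)))
        assert np.abs(st.u).max() < 1e-12
        assert np.abs(st.S).max() < 1e-10

    def test_patch_test_linear_displacement(self, unit_solver):
        """A linear displacement prescribed on the whole boundary is
        reproduced exactly at interior nodes."""
        mesh, _ = unit_solver
        params = SolidParams()
        params.host = params.tumour = MaterialParams(c10=1.0, kappa=30.0)
        solver = SolidSolver(mesh, params)
        A = np.array([[0.01, 0.004, 0.0], [0.0, -0.006, 0.002],
                      [0.003, 0.0, 0.005]])
        u_exact = mesh.nodes @ A.T
        on_bnd = np.any((mesh.nodes < 1e-12) | (mesh.nodes > 1 - 1e-12),
                        axis=1)
        fixed_nodes = np.where(on_bnd)[0]
        fixed_dofs = (3 * fixed_nodes[:, None] + np.arange(3)).ravel()
        fixed_vals = u_exact[fixed_nodes].ravel()
        nel = mesh.n_elems
        Fg = np.tile(np.eye(3), (nel, 8, 1, 1))
        st = solver.solve(Fg, np.ones((nel, 8)), fixed_dofs=fixed_dofs,
                          fixed_vals=fixed_vals)
        assert np.abs(st.u - u_exact).max() < 1e-10

    def test_free_growth_of_uniform_tumour_cube(self):
        """Uniform growth of an all-tumour, traction-free cube produces
        (near-)zero stress and the analytic volume ratio λ_g³."""
        mesh = generate_cube_mesh(1.0, 4, 0.45)
        mesh.tumour_elems[:] = True
        params = SolidParams()
        solver = SolidSolver(mesh, params)
        lam = 1.1
        theta = (lam ** 2 - 1) / 2
        nel = mesh.n_elems
        Fg = np.tile(lam * np.eye(3), (nel, 8, 1, 1))
        # pin rigid-body modes only: node at origin (xyz), node on +x (yz),
        # node on +y (z)
        n0 = int(np.argmin(np.linalg.norm(mesh.nodes, axis=1)))
        nx = int(np.argmin(np.linalg.norm(mesh.nodes - [1, 0, 0], axis=1)))
        ny = int(np.argmin(np.linalg.norm(mesh.nodes - [0, 1, 0], axis=1)))
        fixed = []
        vals = []
        for dof in range(3):
            fixed.append(3 * n0 + dof)
            vals.append((lam - 1) * mesh.nodes[n0, dof])
        for dof in (1, 2):
            fixed.append(3 * nx + dof)
            vals.append((lam - 1) * mesh.nodes[nx, dof])
        fixed.append(3 * ny + 2)
        vals.append((lam - 1) * mesh.nodes[ny, 2])
        st = solver.solve(Fg, np.ones((nel, 8)),
                          fixed_dofs=np.array(fixed),
                          fixed_vals=np.array(vals))
        vol = mesh.element_volumes(st.u).sum()
        assert vol == pytest.approx(lam ** 3, rel=5e-3)
        assert np.abs(st.S).max() < 1e-6 * params.tumour.c10

    def test_growing_sphere_compresses_periphery(self):
        """A growing central tumour produces compressive (positive) THP
        inside/near the tumour and leaves the far field nearly unloaded."""
        mesh = generate_cube_mesh(6.0, 7, 1.6)
        solver = SolidSolver(mesh, SolidParams())
        nel = mesh.n_elems
        theta = np.zeros((nel, 8))
        theta[mesh.tumour_elems] = 0.3
        Fg = np.zeros((nel, 8, 3, 3))
        Fg[:] = np.eye(3)
        lam = np.sqrt(2 * theta + 1)
        Fg *= lam[..., None, None]
        st = solver.solve(Fg, np.ones((nel, 8)))
        thp = st.thp_elem_kpa
        d = np.linalg.norm(mesh.centroids - 3.0, axis=1)
        near = thp[(d < 1.5)]
        far = thp[d > 2.5]
        assert near.max() > 0  # compression in/near the tumour
        assert np.abs(far).max() < near.max()

    def test_thp_magnitude_monotone_in_growth(self):
        mesh = generate_cube_mesh(6.0, 5, 1.5)
        solver = SolidSolver(mesh, SolidParams())
        nel = mesh.n_elems
        peaks = []
        for theta_val in (0.1, 0.25, 0.45):
            theta = np.zeros((nel, 8))
            theta[mesh.tumour_elems] = theta_val
            lam = np.sqrt(2 * theta + 1)
            Fg = np.tile(np.eye(3), (nel, 8, 1, 1)) * lam[..., None, None]
            st = solver.solve(Fg, np.ones((nel, 8)))
            peaks.append(np.abs(st.thp_elem_kpa).max())
        assert peaks[0] < peaks[1] < peaks[2]

    def test_reaction_forces_balance(self, unit_solver):
        """With no external load the total reaction on the pinned faces
        vanishes at equilibrium."""
        mesh, solver = unit_solver
        nel = mesh.n_elems
        theta = np.zeros((nel, 8))
        theta[mesh.tumour_elems] = 0.2
        lam = np.sqrt(2 * theta + 1)
        Fg = np.tile(np.eye(3), (nel, 8, 1, 1)) * lam[..., None, None]
        st = solver.solve(Fg, np.ones((nel, 8)))
        Fg_inv = np.linalg.inv(Fg)
        Jg = np.linalg.det(Fg)
        F, _, C_e = solver._deformation(st.u.ravel(), Fg_inv)
        _, S_ref = solver._sref(C_e, np.ones((nel, 8)), Fg_inv, Jg)
        r = solver._internal_force(F, S_ref)
        free = np.setdiff1d(np.arange(solver.ndof), solver.default_fixed)
        scale = max(np.abs(r).max(), 1e-12)
        assert np.abs(r[free]).max() < 1e-6 * scale
        reactions = r[solver.default_fixed].reshape(-1, 3)
        assert np.abs(reactions.sum(axis=0)).max() < 1e-6 * scale
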