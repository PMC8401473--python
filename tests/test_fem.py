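import numpy as np
import pytest

from breastfem import fem, meshing
from breastfem.fem import (FemConfig, BoundaryConditions, strain_energy,
                           neo_hookean_pk1, neo_hookean_cauchy,
                           solve_gravity, estimate_reference_state,
                           simulate_supine_to_prone, InvertedElementError)
from breastfem.materials import MaterialParams, derive_moduli

from ._linear_fem import solve_linear_gravity


def uniaxial_F(lam):
    """Isochoric uniaxial stretch: J = 1 by construction."""
    return np.diag([lam, lam ** -0.5, lam ** -0.5])


class TestConstitutiveLaw:
    def test_reference_configuration_zero_energy(self):
        assert strain_energy(np.eye(3), 83.9, 4166.7) == 0.0

    @pytest.mark.parametrize("lam", [0.7, 0.85, 1.0, 1.15, 1.3])
    def test_isochoric_uniaxial_energy(self, lam):
        mu, K = derive_moduli(250.0, 0.49)
        psi = strain_energy(uniaxial_F(lam), mu, K)
        # J = 1: volumetric term vanishes, psi = mu/2 (lam^2 + 2/lam - 3)
        assert psi == pytest.approx(0.5 * mu * (lam ** 2 + 2 / lam - 3),
                                    rel=1e-12)

    @pytest.mark.parametrize("alpha", [0.9, 1.0, 1.1])
    def test_pure_dilation_energy(self, alpha):
        mu, K = derive_moduli(250.0, 0.49)
        psi = strain_energy(alpha * np.eye(3), mu, K)
        # isotropic scaling: Ibar1 = 3 exactly, only the K-term remains
        assert psi == pytest.approx(0.5 * K * (alpha ** 3 - 1) ** 2,
                                    rel=1e-12, abs=1e-12)

    @pytest.mark.parametrize("lam", np.linspace(0.7, 1.3, 7))
    def test_uniaxial_cauchy_stress_closed_form(self, lam):
        mu, K = derive_moduli(2.0, 0.49)
        sigma = neo_hookean_cauchy(uniaxial_F(lam), mu, K)
        # J=1: sigma_axial = mu (lam^2 - Ibar1/3), transverse analogous
        I1 = lam ** 2 + 2 / lam
        expected = mu * (lam ** 2 - I1 / 3)
        assert sigma[0, 0] == pytest.approx(expected, rel=1e-10, abs=1e-12)
        assert sigma[1, 1] == pytest.approx(mu * (1 / lam - I1 / 3),
                                            rel=1e-10, abs=1e-12)

    def test_pk1_is_energy_gradient(self):
        rng = np.random.default_rng(0)
        F = np.eye(3) + 0.1 * rng.normal(size=(3, 3))
        mu, K = 80.0, 4000.0
        P = neo_hookean_pk1(F, mu, K)
        eps = 1e-7
        for i in range(3):
            for j in range(3):
                Fp, Fm = F.copy(), F.copy()
                Fp[i, j] += eps
                Fm[i, j] -= eps
                fd = (strain_energy(Fp, mu, K)
                      - strain_energy(Fm, mu, K)) / (2 * eps)
                assert P[i, j] == pytest.approx(fd, rel=1e-5, abs=1e-8)

    def test_inverted_deformation_rejected(self):
        with pytest.raises(InvertedElementError):
            strain_energy(np.diag([-1.0, 1.0, 1.0]), 80.0, 4000.0)


class TestAssemblerConsistency:
    """Discrete residual and tangent are exact derivatives of the energy."""

    @pytest.fixture(scope="class")
    def assembler(self, hemi_mesh, materials):
        return fem._Assembler(hemi_mesh, materials, FemConfig())

    def test_residual_is_energy_gradient(self, assembler):
        rng = np.random.default_rng(1)
        u = rng.normal(scale=0.05, size=assembler.ndof)
        f = assembler.internal_force(u)
        eps = 1e-6
        for i in rng.choice(assembler.ndof, 10, replace=False):
            up, um = u.copy(), u.copy()
            up[i] += eps
            um[i] -= eps
            fd = (assembler.energy(up) - assembler.energy(um)) / (2 * eps)
            assert fd == pytest.approx(f[i], rel=2e-6, abs=2e-6)

    def test_tangent_matches_residual_derivative_in_tension(self, assembler,
                                                            hemi_mesh):
        # inflate slightly so the membrane is taut everywhere (where the
        # wrinkling-stabilized tangent equals the exact one)
        rng = np.random.default_rng(2)
        u = 0.02 * hemi_mesh.nodes.ravel() + rng.normal(scale=0.004,
                                                        size=assembler.ndof)
        K = assembler.tangent(u).toarray()
        assert np.abs(K - K.T).max() <= 1e-10 * np.abs(K).max()
        eps = 1e-6
        for i in rng.choice(assembler.ndof, 4, replace=False):
            up, um = u.copy(), u.copy()
            up[i] += eps
            um[i] -= eps
            fd = (assembler.internal_force(up)
                  - assembler.internal_force(um)) / (2 * eps)
            err = np.abs(fd - K[:, i]).max() / max(1.0, np.abs(K[:, i]).max())
            assert err < 1e-5

    def test_rigid_translation_zero_internal_force(self, assembler):
        u = np.tile([3.0, -2.0, 1.0], assembler.mesh.n_nodes)
        f = assembler.internal_force(u)
        assert np.abs(f).max() < 1e-8

    def test_single_cube_reaction_matches_closed_form(self,
                                                      single_element_mesh,
                                                      materials):
        # prescribe an isochoric uniaxial stretch on the single element and
        # compare the top-face reaction with the closed-form PK1 traction
        mesh = single_element_mesh
        cfg = FemConfig(skin_model="none")
        asm = fem._Assembler(mesh, materials, cfg)
        lam = 1.2
        X = mesh.nodes - mesh.nodes.mean(axis=0)
        F = uniaxial_F(lam)
        u = (X @ F.T - X).reshape(-1)
        forces = asm.internal_force(u).reshape(-1, 3)
        top = mesh.nodes[:, 1] == mesh.nodes[:, 1].max()
        reaction = forces[top, 1].sum()
        t = materials.adipose
        P = neo_hookean_pk1(F, t.mu, t.K)
        area0 = 4.0     # 2 mm x 2 mm reference face
        assert reaction == pytest.approx(P[1, 1] * area0, rel=1e-2)


class TestGravitySolve:
    def test_zero_gravity_zero_displacement(self, hemi_mesh, materials):
        bc = BoundaryConditions.for_posture(hemi_mesh, "none")
        d = solve_gravity(hemi_mesh, materials, bc)
        assert d.converged
        np.testing.assert_array_equal(d.u, 0.0)
        assert d.newton_iterations == 1

    def test_small_gravity_matches_linear_oracle(self, hemi_mesh, materials):
        # at g scaled by 1e-3 the response is linear; compare with the
        # independently implemented linear-elastic solver
        cfg = FemConfig(gravity_magnitude=9.81e-3, skin_model="none")
        bc = BoundaryConditions.prone(hemi_mesh, cfg)
        d = solve_gravity(hemi_mesh, materials, bc, cfg)
        E = np.where(hemi_mesh.element_tissue == meshing.TISSUE_ADIPOSE,
                     materials.adipose.E, materials.fibroglandular.E)
        rho = np.where(hemi_mesh.element_tissue == meshing.TISSUE_ADIPOSE,
                       materials.adipose.rho, materials.fibroglandular.rho)
        u_lin = solve_linear_gravity(hemi_mesh.nodes, hemi_mesh.elements,
                                     E, 0.49, rho, bc.gravity, bc.fixed)
        scale = np.linalg.norm(u_lin, axis=1).max()
        err = np.linalg.norm(d.u - u_lin, axis=1).max()
        assert err <= 0.02 * scale

    def test_chest_wall_fixed_in_ap(self, hemi_mesh, materials,
                                    fast_fem_config):
        bc = BoundaryConditions.prone(hemi_mesh, fast_fem_config)
        d = solve_gravity(hemi_mesh, materials, bc, fast_fem_config)
        ap = hemi_mesh.ap_axis
        assert np.abs(d.u[hemi_mesh.chest_wall_nodes, ap]).max() < 1e-12

    def test_near_incompressibility_of_converged_solve(self, hemi_mesh,
                                                       fast_fem_config):
        soft = MaterialParams().with_adipose_E(8.0)
        bc = BoundaryConditions.prone(hemi_mesh, fast_fem_config)
        d = solve_gravity(hemi_mesh, soft, bc, fast_fem_config)
        asm = fem._Assembler(hemi_mesh, soft, fast_fem_config)
        ue = d.u[hemi_mesh.elements]
        F = asm._defgrad(ue, asm.gradN_vol)
        J = np.linalg.det(F)
        assert np.abs(J - 1).max() <= 0.05

    def test_softer_tissue_sags_more(self, hemi_mesh, fast_fem_config):
        bc = BoundaryConditions.prone(hemi_mesh, fast_fem_config)
        nips = []
        for E in (50.0, 10.0):
            d = solve_gravity(hemi_mesh, MaterialParams().with_adipose_E(E),
                              bc, fast_fem_config)
            nips.append(d.nipple_displacement())
        assert nips[1] > nips[0]


class TestReferenceState:
    def test_zero_gravity_returns_input(self, hemi_mesh, materials):
        cfg = FemConfig(gravity_magnitude=0.0)
        ref = estimate_reference_state(hemi_mesh, materials, cfg)
        np.testing.assert_allclose(ref.nodes, hemi_mesh.nodes, atol=1e-12)

    def test_round_trip_reproduces_supine_surface(self, hemi_mesh,
                                                  fast_fem_config):
        mats = MaterialParams().with_adipose_E(10.0)
        ref = estimate_reference_state(hemi_mesh, mats, fast_fem_config)
        bc = BoundaryConditions.supine(ref, fast_fem_config)
        d = solve_gravity(ref, mats, bc, fast_fem_config)
        x_pred = ref.nodes + d.u
        surf = hemi_mesh.surface_node_set()
        err = np.linalg.norm(x_pred[surf] - hemi_mesh.nodes[surf],
                             axis=1).mean()
        assert err < 0.5

    def test_supine_to_prone_identity_without_gravity(self, hemi_mesh,
                                                      materials):
        cfg = FemConfig(gravity_magnitude=0.0)
        d = simulate_supine_to_prone(hemi_mesh, materials, cfg)
        np.testing.assert_array_equal(d.u, 0.0)

    def test_nipple_displacement_monotone_in_modulus(self, hemi_mesh,
                                                     fast_fem_config):
        # stiffer breast sags less, over a modulus ladder
        warm = None
        nips = []
        for E in (250.0, 64.0, 16.0, 8.0, 4.0):
            d = simulate_supine_to_prone(
                hemi_mesh, MaterialParams().with_adipose_E(E),
                fast_fem_config, warm=warm)
            warm = d
            nips.append(d.nipple_displacement())
        assert all(b > a for a, b in zip(nips, nips[1:]))
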