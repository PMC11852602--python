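"""FE elasticity verification: patch tests, beam oracle, equilibrium,
principal/von Mises stress algebra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from osteostim import generate_block_fixture, principal_stresses, von_mises
from osteostim.elasticity import solve_elasticity, LoadCase
from osteostim._fem import SingularSystemError, BadMaterialError


def _roller_bcs(mesh):
    return [
        (mesh.facet_set_nodes("zmin"), 2, 0.0),
        (mesh.facet_set_nodes("xmin"), 0, 0.0),
        (mesh.facet_set_nodes("ymin"), 1, 0.0),
    ]


class TestPatchAndEquilibrium:
    @pytest.mark.parametrize("order", [1, 2])
    def test_uniaxial_patch(self, order):
        """Uniform traction with roller supports reproduces constant stress
        exactly on both linear and quadratic tetrahedra."""
        mesh = generate_block_fixture(2, 2, 2, (10.0, 10.0, 10.0))
        if order == 2:
            mesh = mesh.to_quadratic()
        p = 5.0
        u, sigma, _ = solve_elasticity(
            mesh, np.full(mesh.n_elements, 1000.0), np.full(mesh.n_elements, 0.3),
            _roller_bcs(mesh), {"zmax": np.array([0.0, 0.0, p * 100.0])})
        vm = von_mises(principal_stresses(sigma))
        assert np.max(np.abs(vm - p)) <= 1e-8 * p
        assert np.max(np.abs(sigma[:, 2, 2] - p)) <= 1e-8 * p

    def test_zero_load_zero_response(self, block_mesh):
        u, sigma, _ = solve_elasticity(
            block_mesh, np.full(block_mesh.n_elements, 1000.0), 0.3,
            [(block_mesh.facet_set_nodes("zmin"), None, 0.0)],
            {"zmax": np.zeros(3)})
        assert np.max(np.abs(u)) == 0.0
        assert np.max(np.abs(sigma)) == 0.0

    def test_reactions_balance_applied_load(self, block_mesh):
        force = np.array([30.0, -10.0, -200.0])
        _, _, reactions = solve_elasticity(
            block_mesh, np.full(block_mesh.n_elements, 1000.0), 0.3,
            [(block_mesh.facet_set_nodes("zmin"), None, 0.0)],
            {"zmax": force})
        total = reactions.reshape(-1, 3).sum(axis=0)
        assert np.allclose(total, -force, rtol=1e-6)

    def test_beam_tip_deflection_matches_euler_bernoulli(self):
        """Slender cantilever (L/h = 20), quadratic elements: tip deflection
        within 5% of P L^3 / (3 E I)."""
        L, b, h, E, P = 40.0, 2.0, 2.0, 1000.0, 1.0
        mesh = generate_block_fixture(20, 2, 2, (L, b, h)).to_quadratic()
        u, _, _ = solve_elasticity(
            mesh, np.full(mesh.n_elements, E), np.full(mesh.n_elements, 0.0),
            [(mesh.facet_set_nodes("xmin"), None, 0.0)],
            {"xmax": np.array([0.0, 0.0, -P])})
        tip = u.reshape(-1, 3)[mesh.facet_set_nodes("xmax"), 2].mean()
        exact = -P * L ** 3 / (3 * E * (b * h ** 3 / 12))
        assert abs(tip / exact - 1) < 0.05

    def test_strain_energy_increases_under_refinement(self):
        """Displacement FEM underestimates compliance; refining the beam
        raises the strain energy toward the exact value."""
        energies = []
        for cells in ((10, 1, 1), (20, 2, 2)):
            mesh = generate_block_fixture(*cells, (40.0, 2.0, 2.0))
            f_ext = {"xmax": np.array([0.0, 0.0, -1.0])}
            u, _, _ = solve_elasticity(
                mesh, np.full(mesh.n_elements, 1000.0), 0.0,
                [(mesh.facet_set_nodes("xmin"), None, 0.0)], f_ext)
            tip = u.reshape(-1, 3)[mesh.facet_set_nodes("xmax"), 2].mean()
            energies.append(-0.5 * tip)   # work of the unit tip load
        assert energies[1] > energies[0]

    def test_no_constraints_is_singular(self, block_mesh):
        with pytest.raises(SingularSystemError):
            solve_elasticity(block_mesh, np.full(block_mesh.n_elements, 1000.0),
                             0.3, [], {"zmax": np.array([0.0, 0.0, 1.0])})

    def test_nonpositive_modulus_rejected(self, block_mesh):
        E = np.full(block_mesh.n_elements, 1000.0)
        E[0] = 0.0
        with pytest.raises(BadMaterialError):
            solve_elasticity(block_mesh, E, 0.3,
                             [(block_mesh.facet_set_nodes("zmin"), None, 0.0)],
                             {"zmax": np.array([0.0, 0.0, 1.0])})


class TestStressAlgebra:
    def test_principal_of_diagonal(self):
        assert np.allclose(principal_stresses(np.diag([3.0, 1.0, -2.0])),
                           [3.0, 1.0, -2.0])

    def test_hydrostatic(self):
        p = 7.3
        assert np.allclose(principal_stresses(p * np.eye(3)), [p, p, p])
        assert von_mises(np.array([p, p, p])) == pytest.approx(0.0, abs=1e-12)

    def test_asymmetric_rejected(self):
        t = np.diag([1.0, 2.0, 3.0])
        t[0, 1] = 1e-3
        with pytest.raises(ValueError):
            principal_stresses(t)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(deadline=None, max_examples=30)
    def test_invariants_preserved(self, seed):
        """Trace and determinant survive the eigendecomposition."""
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(3, 3))
        t = 0.5 * (a + a.T)
        p = principal_stresses(t)
        assert np.all(np.diff(p) <= 0)
        assert np.isclose(p.sum(), np.trace(t), atol=1e-10)
        assert np.isclose(np.prod(p), np.linalg.det(t), atol=1e-10)

    @pytest.mark.parametrize("principal,expected", [
        ((5.0, 0.0, 0.0), 5.0),
        ((3.0, 1.0, -2.0), np.sqrt(19.0)),
    ])
    def test_von_mises_values(self, principal, expected):
        assert von_mises(np.array(principal)) == pytest.approx(expected, rel=1e-12)

    @given(st.floats(-100, 100), st.floats(-100, 100), st.floats(-100, 100),
           st.floats(-50, 50))
    @settings(deadline=None, max_examples=50)
    def test_hydrostatic_offset_invariance(self, s1, s2, s3, p):
        base = von_mises(np.array([s1, s2, s3]))
        shifted = von_mises(np.array([s1 + p, s2 + p, s3 + p]))
        assert shifted == pytest.approx(base, rel=1e-9, abs=1e-9)


class TestLoadCase:
    def test_direction_convention(self):
        lc = LoadCase("standing", 6000, 2317.0, 24.0, 703.0, 28.0)
        forces = lc.force_vectors()
        joint = forces["head_surface"]
        # compressive: pushes down the shaft axis, tilted medially
        assert joint[2] < 0 and joint[0] < 0
        assert np.isclose(np.linalg.norm(joint), 2317.0)
        muscle = forces["greater_trochanter"]
        assert muscle[2] > 0
        assert np.isclose(np.linalg.norm(muscle), 703.0)

    def test_negative_angle_flips_side(self):
        lc = LoadCase("abduction", 2000, 1158.0, -15.0, 351.0, -8.0)
        assert lc.force_vectors()["head_surface"][0] > 0

    def test_invalid_cycles_rejected(self):
        with pytest.raises(ValueError):
            LoadCase("x", 0, 1.0, 0.0, 1.0, 0.0)
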