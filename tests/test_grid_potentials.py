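import numpy as np
import pytest

from etcomplex.constants import COULOMB_KJ_A, WATER_DIELECTRIC
from etcomplex.grid_potentials import (
    PotentialGrid,
    assign_lj_categories,
    build_gridset,
    electrostatic_grid,
    interpolate,
    lj_grid,
    smooth_grid,
)
from etcomplex.rigid_body_bd import RigidState, interaction_energy
from etcomplex.structure_props import AtomSet, load_atom_params
from etcomplex.toys import bead_body

from helpers import pairwise_reference_energy


def _atoms(coords, elements, charges=None):
    n = len(coords)
    return AtomSet(
        coords=np.asarray(coords, dtype=float),
        elements=np.asarray(elements, dtype=object),
        charges=np.zeros(n) if charges is None else np.asarray(charges, dtype=float),
        masses=np.full(n, 12.0),
    )


class TestCategories:
    def test_mapping_and_averaging(self):
        atoms = _atoms([[0, 0, 0], [3, 0, 0]], ["C", "S"])
        atoms, params = assign_lj_categories(atoms)
        table = load_atom_params()
        assert list(atoms.categories) == ["CS", "CS"]
        assert params.rmin_half_A["CS"] == pytest.approx(
            (table.loc["C", "rmin_half_A"] + table.loc["S", "rmin_half_A"]) / 2
        )
        assert params.epsilon_kJ_mol["CS"] == pytest.approx(
            (table.loc["C", "epsilon_kJ_mol"] + table.loc["S", "epsilon_kJ_mol"]) / 2
        )

    def test_all_hydrogen_input(self):
        atoms = _atoms([[0, 0, 0], [1, 0, 0]], ["H", "H"])
        atoms, params = assign_lj_categories(atoms)
        assert set(atoms.categories) == {"H"}
        assert params.rmin_half_A["H"] > 0

    def test_averages_match_brute_force(self):
        rng = np.random.default_rng(0)
        elements = rng.choice(["H", "C", "N", "O", "S"], 40)
        atoms = _atoms(rng.normal(0, 5, (40, 3)), elements)
        atoms, params = assign_lj_categories(atoms)
        table = load_atom_params()
        members = [e for e in elements if e in ("O", "N")]
        expected = np.mean([table.loc[e, "rmin_half_A"] for e in members])
        assert params.rmin_half_A["ON"] == pytest.approx(expected)

    def test_unknown_element_falls_back_with_warning(self):
        atoms = _atoms([[0, 0, 0]], ["ZN"])
        with pytest.warns(UserWarning):
            atoms, _ = assign_lj_categories(atoms)
        assert atoms.categories[0] == "CS"


class TestElectrostaticGrid:
    def test_unscreened_coulomb_closed_form(self):
        # +1e charge; potential at 10 A with no screening
        atoms = _atoms([[0.0, 0.0, 0.0]], ["N"], charges=[1.0])
        g = electrostatic_grid(atoms, ionic_strength_mM=0.0, spacing=1.0, margin_A=12.0)
        val, _ = interpolate(g, np.array([10.0, 0.0, 0.0]))
        assert val == pytest.approx(COULOMB_KJ_A / WATER_DIELECTRIC / 10.0, rel=1e-6)

    def test_sign_flip_linearity(self):
        pos = _atoms([[0.0, 0, 0]], ["N"], charges=[1.0])
        neg = _atoms([[0.0, 0, 0]], ["N"], charges=[-1.0])
        gp = electrostatic_grid(pos, 100.0, spacing=2.0, margin_A=10.0)
        gn = electrostatic_grid(neg, 100.0, spacing=2.0, margin_A=10.0)
        assert np.allclose(gp.values, -gn.values)

    def test_screening_monotonic(self):
        atoms = _atoms([[0.0, 0, 0]], ["N"], charges=[1.0])
        probe = np.array([8.0, 0.0, 0.0])
        vals = []
        for salt in (10.0, 100.0, 500.0):
            g = electrostatic_grid(atoms, salt, spacing=1.0, margin_A=12.0)
            vals.append(interpolate(g, probe)[0])
        assert vals[0] > vals[1] > vals[2] > 0


class TestLJGrid:
    def test_far_node_near_zero_and_minimum_depth(self):
        atoms = _atoms([[0.0, 0.0, 0.0]], ["C"])
        atoms, params = assign_lj_categories(atoms)
        g = lj_grid(atoms, params, "CS", spacing=0.5, margin_A=32.0)
        table = load_atom_params()
        rmin = params.rmin_half_A["CS"] + table.loc["C", "rmin_half_A"]
        eps = np.sqrt(params.epsilon_kJ_mol["CS"] * table.loc["C", "epsilon_kJ_mol"])
        far, _ = interpolate(g, np.array([31.0, 0.0, 0.0]))
        assert abs(far) < 1e-3
        at_min, _ = interpolate(g, np.array([rmin, 0.0, 0.0]))
        assert at_min == pytest.approx(-eps, abs=0.02 * eps + 1e-3)

    def test_nodes_match_direct_sum(self):
        rng = np.random.default_rng(1)
        atoms = _atoms(rng.normal(0, 3, (10, 3)), ["C"] * 10)
        atoms, params = assign_lj_categories(atoms)
        g = lj_grid(atoms, params, "H", spacing=1.0, margin_A=8.0, cap_kJ_mol=100.0)
        table = load_atom_params()
        rmin = params.rmin_half_A["H"] + table.loc["C", "rmin_half_A"]
        eps = np.sqrt(params.epsilon_kJ_mol["H"] * table.loc["C", "epsilon_kJ_mol"])
        axes = g.axes()
        for _ in range(20):
            idx = tuple(rng.integers(0, n) for n in g.dims)
            node = np.array([axes[0][idx[0]], axes[1][idx[1]], axes[2][idx[2]]])
            d = np.maximum(np.linalg.norm(node - atoms.coords, axis=1), 1e-3)
            sr6 = (rmin / d) ** 6
            ref = min((eps * (sr6**2 - 2 * sr6)).sum(), 100.0)
            assert g.values[idx] == pytest.approx(ref, abs=1e-9)


class TestSmoothing:
    def test_constant_field_unchanged(self):
        g = PotentialGrid(np.zeros(3), 1.0, np.full((8, 8, 8), 3.7), "electrostatic")
        s = smooth_grid(g, 1.0)
        assert np.allclose(s.values, 3.7)

    def test_delta_spike_gaussian_width(self):
        v = np.zeros((21, 21, 21))
        v[10, 10, 10] = 1.0
        g = PotentialGrid(np.zeros(3), 1.0, v, "electrostatic")
        s = smooth_grid(g, 1.0)
        # second moment of the smoothed profile along one axis = sigma^2
        prof = s.values.sum(axis=(1, 2))
        x = np.arange(21) - 10.0
        var = (prof * x**2).sum() / prof.sum()
        assert var == pytest.approx(1.0, abs=0.05)
        assert s.values.sum() == pytest.approx(1.0, rel=1e-3)

    def test_repeated_smoothing_composes_in_quadrature(self):
        v = np.zeros((31, 31, 31))
        v[15, 15, 15] = 1.0
        g = PotentialGrid(np.zeros(3), 1.0, v, "electrostatic")
        twice = smooth_grid(smooth_grid(g, 1.0), 1.0)
        once = smooth_grid(g, np.sqrt(2.0))
        assert np.allclose(twice.values, once.values, atol=2e-3)


class TestInterpolate:
    def test_node_exact(self):
        rng = np.random.default_rng(2)
        g = PotentialGrid(np.array([1.0, 2, 3]), 1.5, rng.normal(size=(5, 6, 7)), "electrostatic")
        val, _ = interpolate(g, g.origin + 1.5 * np.array([2, 3, 4]))
        assert val == pytest.approx(g.values[2, 3, 4], rel=1e-12)

    def test_linear_field_exact_gradient(self):
        axes = [np.arange(6, dtype=float)] * 3
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        g = PotentialGrid(np.zeros(3), 1.0, 2.0 * X - 3.0 * Y + 0.5 * Z, "electrostatic")
        val, grad = interpolate(g, np.array([2.3, 1.7, 4.1]))
        assert val == pytest.approx(2 * 2.3 - 3 * 1.7 + 0.5 * 4.1, rel=1e-12)
        assert np.allclose(grad, [2.0, -3.0, 0.5])

    def test_gradient_matches_finite_differences(self):
        atoms = _atoms([[0.0, 0, 0]], ["N"], charges=[1.0])
        g = electrostatic_grid(atoms, 100.0, spacing=1.0, margin_A=10.0)
        p = np.array([4.3, 2.1, -3.7])
        _, grad = interpolate(g, p)
        h = 1e-5
        for k in range(3):
            dp = np.zeros(3)
            dp[k] = h
            fd = (interpolate(g, p + dp)[0] - interpolate(g, p - dp)[0]) / (2 * h)
            assert grad[k] == pytest.approx(fd, abs=1e-5)

    def test_outside_bounds_rejected(self):
        g = PotentialGrid(np.zeros(3), 1.0, np.zeros((4, 4, 4)), "electrostatic")
        with pytest.raises(ValueError):
            interpolate(g, np.array([10.0, 0.0, 0.0]))


class TestGridEnergyConvergence:
    def test_error_decreases_as_spacing_halves(self):
        """Grid-interpolated body energy converges to the direct pairwise
        Debye-Hueckel + LJ sum as spacing goes 2 -> 1 -> 0.5 A."""
        rng = np.random.default_rng(3)
        receptor = _atoms(
            rng.normal(0, 3, (12, 3)),
            list(rng.choice(["C", "N", "O"], 12)),
            charges=rng.choice([-0.5, 0.5], 12),
        )
        body_atoms = bead_body()
        from etcomplex.grid_potentials import assign_lj_categories as alc

        alc(body_atoms)
        pose = RigidState(position=np.array([0.0, 0.0, 12.0]))
        from etcomplex.structure_props import build_mobile_body

        body = build_mobile_body(body_atoms)
        pts = body.atoms.coords - body.center_of_mass + pose.position
        ref = pairwise_reference_energy(
            body.atoms,
            list(body.atoms.categories),
            build_gridset(receptor, 100.0, spacing=2.0, margin_A=10.0, smoothing_width_A=0.0, mobile_atoms=body_atoms).category_params,
            receptor,
            pts,
            100.0,
        )
        errors = []
        for spacing in (2.0, 1.0, 0.5):
            grids = build_gridset(
                receptor,
                100.0,
                spacing=spacing,
                margin_A=10.0,
                smoothing_width_A=0.0,
                mobile_atoms=body_atoms,
            )
            e = interaction_energy(pose, body, grids)
            errors.append(abs(e - ref))
        assert errors[0] > errors[1] > errors[2]
        # residual discretization error at 0.5 A, dominated by the steep LJ
        # wall nearest the receptor
        assert errors[2] < 0.1
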