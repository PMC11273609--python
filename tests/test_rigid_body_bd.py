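import numpy as np
import pytest

from etcomplex.constants import kbt_kj_mol
from etcomplex.grid_potentials import assign_lj_categories, build_gridset
from etcomplex.rigid_body_bd import (
    BDParams,
    RigidState,
    _quat_to_matrix,
    bd_step,
    interaction_energy,
    run_trajectory,
    steered_pull,
)
from etcomplex.structure_props import build_mobile_body
from etcomplex.toys import bead_body, two_site_receptor

from helpers import pairwise_reference_energy


class TestBDStep:
    def test_force_free_deterministic_limit(self, toy_body):
        params = BDParams(temperature_K=0.0, duration_ns=1.0)
        state = RigidState(position=np.array([1.0, 2.0, 3.0]))
        rng = np.random.default_rng(0)
        new = bd_step(state, toy_body, None, params, rng)
        assert np.allclose(new.position, state.position)
        assert np.allclose(new.quaternion, state.quaternion)

    def test_quaternion_stays_normalized(self, toy_body):
        params = BDParams(duration_ns=1.0, seed=0)
        rng = np.random.default_rng(1)
        state = RigidState(position=np.zeros(3))
        for _ in range(200):
            state = bd_step(state, toy_body, None, params, rng)
            assert np.linalg.norm(state.quaternion) == pytest.approx(1.0, abs=1e-9)

    def test_free_diffusion_msd(self, toy_body):
        """Ensemble MSD of free diffusion equals 6 D t within 5%."""
        params = BDParams(duration_ns=1.0)
        n_steps = 60
        disp = []
        for r in range(600):
            rng = np.random.default_rng(5000 + r)
            s = RigidState(position=np.zeros(3))
            for _ in range(n_steps):
                s = bd_step(s, toy_body, None, params, rng)
            disp.append(s.position)
        msd = (np.asarray(disp) ** 2).sum(axis=1).mean()
        expected = 6 * toy_body.D_trans[0] * n_steps * params.dt_ns
        assert msd == pytest.approx(expected, rel=0.05)

    def test_harmonic_well_equipartition(self, toy_body):
        """Positional variance in a harmonic well equals kBT/k within 5%."""
        k = 20.0
        well = lambda pos, t: (0.5 * k * float(pos @ pos), -k * pos)
        params = BDParams(duration_ns=1.0)
        samples = []
        for r in range(12):
            rng = np.random.default_rng(7000 + r)
            s = RigidState(position=np.zeros(3))
            for i in range(6000):
                s = bd_step(s, toy_body, None, params, rng, external=well)
                if i > 500 and i % 10 == 0:
                    samples.append(s.position.copy())
        var = np.asarray(samples).var(axis=0).mean()
        assert var == pytest.approx(kbt_kj_mol(300.0) / k, rel=0.05)

    def test_free_rotational_diffusion_decay(self, toy_body):
        """Orientational correlation decays as exp(-2 D_r t) within 10%."""
        params = BDParams(duration_ns=1.0)
        n_steps = 200
        cos_theta = []
        for r in range(400):
            rng = np.random.default_rng(9000 + r)
            s = RigidState(position=np.zeros(3))
            for _ in range(n_steps):
                s = bd_step(s, toy_body, None, params, rng)
            cos_theta.append(_quat_to_matrix(s.quaternion)[2, 2])
        expected = np.exp(-2 * toy_body.D_rot[0] * n_steps * params.dt_ns)
        assert np.mean(cos_theta) == pytest.approx(expected, rel=0.10)


class TestRunTrajectory:
    def test_frame_bookkeeping(self, toy_body):
        params = BDParams(duration_ns=1.0, record_every_ns=1.0, seed=0)
        traj = run_trajectory(toy_body, None, params, RigidState(position=np.zeros(3)))
        assert len(traj) == 2
        assert traj.times_ns[0] == 0.0
        assert traj.times_ns[-1] == pytest.approx(1.0)

    def test_seed_reproducibility(self, toy_body):
        params = BDParams(duration_ns=0.05, record_every_ns=0.01, seed=11)
        a = run_trajectory(toy_body, None, params, RigidState(position=np.zeros(3)))
        b = run_trajectory(toy_body, None, params, RigidState(position=np.zeros(3)))
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.quaternions, b.quaternions)

    def test_occupancy_grows_with_well_depth(self, toy_body):
        """Time near the attractive site increases with well depth."""
        from etcomplex.toys import single_well_receptor

        fractions = []
        for q in (-1.0, -3.0, -6.0):
            receptor, ann = single_well_receptor(well_charge_e=q)
            grids = build_gridset(receptor, 10.0, spacing=1.0, margin_A=14.0)
            params = BDParams(duration_ns=1.5, record_every_ns=0.01, seed=21)
            traj = run_trajectory(
                toy_body, grids, params, RigidState(position=np.array([0.0, 0.0, 12.0]))
            )
            d = np.linalg.norm(traj.positions - ann["well"], axis=1)
            fractions.append((d < 7.0).mean())
        assert fractions[0] < fractions[2]
        assert fractions[1] <= fractions[2] + 0.05


class TestInteractionEnergy:
    def test_far_pose_near_zero(self, toy_body):
        # strong screening (250 mM, Debye length ~5 A) so a pose tens of
        # Angstroms from the receptor is genuinely outside interaction range
        receptor, _ = two_site_receptor()
        grids = build_gridset(receptor, ionic_strength_mM=250.0, spacing=1.5, margin_A=30.0)
        far = RigidState(position=grids.electrostatic.upper - 5.0)
        assert abs(interaction_energy(far, toy_body, grids)) < 0.2

    def test_matches_direct_pairwise_sum(self, two_well_system):
        receptor, ann, grids, body = two_well_system
        pose = RigidState(position=np.array([-14.0, 0.0, 10.0]))
        pts = body.atoms.coords - body.center_of_mass + pose.position
        ref = pairwise_reference_energy(
            body.atoms,
            list(body.atoms.categories),
            grids.category_params,
            receptor,
            pts,
            10.0,
        )
        e = interaction_energy(pose, body, grids)
        # grid discretization + smoothing tolerance
        assert e == pytest.approx(ref, abs=0.15 * abs(ref) + 0.5)

    def test_invariant_under_simultaneous_rotation(self, toy_body):
        """90-degree rotation of receptor and pose about z leaves energy unchanged."""
        receptor, ann = two_site_receptor()
        Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        from etcomplex.structure_props import AtomSet

        rotated = AtomSet(
            coords=receptor.coords @ Rz.T,
            elements=receptor.elements,
            charges=receptor.charges,
            masses=receptor.masses,
        )
        g0 = build_gridset(receptor, 10.0, spacing=1.0, margin_A=12.0)
        g1 = build_gridset(rotated, 10.0, spacing=1.0, margin_A=12.0)
        p = np.array([-14.0, 0.0, 10.0])
        q_body = np.array([1.0, 0.0, 0.0, 0.0])
        q_rot = np.array([np.cos(np.pi / 4), 0.0, 0.0, np.sin(np.pi / 4)])  # 90 deg about z
        e0 = interaction_energy(RigidState(position=p, quaternion=q_body), toy_body, g0)
        e1 = interaction_energy(RigidState(position=Rz @ p, quaternion=q_rot), toy_body, g1)
        assert e1 == pytest.approx(e0, abs=0.02 * abs(e0) + 0.05)


class TestSteeredPull:
    def test_zero_potential_flat_profile(self, toy_body):
        receptor, _ = two_site_receptor(proximal_charge_e=0.0, distal_charge_e=0.0)
        receptor.charges[:] = 0.0
        grids = build_gridset(receptor, 100.0, spacing=1.5, margin_A=14.0)
        params = BDParams(timestep_fs=200.0, seed=4)
        prof = steered_pull(
            toy_body,
            grids,
            [-18.0, 0.0, 13.0],
            [18.0, 0.0, 13.0],
            velocity_A_per_ns=8.0,
            spring_k=10.0,
            params=params,
            record_every_ns=0.05,
        )
        assert prof.energy_kJ_mol.abs().max() < 1.5

    def test_two_trough_fixture_positions(self, toy_body):
        receptor, _ = two_site_receptor(proximal_charge_e=-8.0, distal_charge_e=-8.0)
        grids = build_gridset(receptor, 100.0, spacing=1.0, margin_A=12.0)
        params = BDParams(timestep_fs=200.0, seed=5)
        prof = steered_pull(
            toy_body,
            grids,
            [-24.0, 0.0, 9.0],
            [24.0, 0.0, 9.0],
            velocity_A_per_ns=4.0,
            spring_k=10.0,
            params=params,
            record_every_ns=0.05,
        )
        from etcomplex.binding_analysis import detect_states

        states = detect_states(prof, smoothing_window=5, prominence_kJ_mol=2.0)
        positions = [s[0] for s in states]
        # wells at x = +/-14, site point at x = 24 -> rc = 10 and 38
        assert any(abs(p - 10.0) <= 2.0 for p in positions)
        assert any(abs(p - 38.0) <= 2.0 for p in positions)
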