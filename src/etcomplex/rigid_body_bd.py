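"""Overdamped rigid-body Brownian dynamics over receptor potential grids.

The mobile protein is propagated with an Ermak-McCammon scheme: at each
100 fs step the grid forces and torques on the rigid body are evaluated by
trilinear interpolation, the center of mass is displaced by mobility * force
* dt plus a Gaussian kick satisfying fluctuation-dissipation exactly, and
the orientation is updated by the rotational analogue in the principal body
frame, with the quaternion renormalized every step.  A harmonic wall at the
grid margin confines the particle (the original system is confined by its
periodic membrane instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .constants import kbt_kj_mol
from .grid_potentials import GridSet
from .structure_props import MobileBody

__all__ = [
    "RigidState",
    "BDParams",
    "Trajectory",
    "bd_step",
    "run_trajectory",
    "interaction_energy",
    "steered_pull",
]

#: harmonic wall stiffness at the grid margin, kJ/mol/Angstrom^2
WALL_K = 10.0


@dataclass
class RigidState:
    """Position (Angstrom, COM), orientation (unit quaternion wxyz), time (ns)."""

    position: np.ndarray
    quaternion: np.ndarray = field(default_factory=lambda: np.array([1.0, 0, 0, 0]))
    time_ns: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.quaternion = np.asarray(self.quaternion, dtype=float)
        n = np.linalg.norm(self.quaternion)
        if abs(n - 1.0) > 1e-6:
            raise ValueError("quaternion must be unit norm")
        self.quaternion = self.quaternion / n


@dataclass(frozen=True)
class BDParams:
    """Propagation settings: 100 fs step, 300 K, frames recorded every 1 ns."""

    timestep_fs: float = 100.0
    temperature_K: float = 300.0
    record_every_ns: float = 1.0
    duration_ns: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.timestep_fs <= 0 or self.duration_ns <= 0:
            raise ValueError("timestep and duration must be positive")

    @property
    def dt_ns(self) -> float:
        return self.timestep_fs * 1e-6


@dataclass
class Trajectory:
    """Recorded frames of one replica."""

    times_ns: np.ndarray
    positions: np.ndarray  # (n, 3)
    quaternions: np.ndarray  # (n, 4)
    energies_kJ_mol: np.ndarray
    params: BDParams
    seed: int

    def __len__(self) -> int:
        return len(self.times_ns)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ns": self.times_ns,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "qw": self.quaternions[:, 0],
                "qx": self.quaternions[:, 1],
                "qy": self.quaternions[:, 2],
                "qz": self.quaternions[:, 3],
                "energy_kJ_mol": self.energies_kJ_mol,
            }
        )


# ------------------------------------------------------------------ quaternions


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    aw, ax, ay, az = a
    bw, bx, by, bz = b
    return np.array(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ]
    )


def _rotvec_to_quat(v: np.ndarray) -> np.ndarray:
    angle = np.linalg.norm(v)
    if angle < 1e-12:
        return np.array([1.0, 0.5 * v[0], 0.5 * v[1], 0.5 * v[2]])
    axis = v / angle
    s = np.sin(0.5 * angle)
    return np.array([np.cos(0.5 * angle), s * axis[0], s * axis[1], s * axis[2]])


# ------------------------------------------------------------- force evaluation


def _body_points(state: RigidState, body: MobileBody) -> tuple[np.ndarray, np.ndarray]:
    R = _quat_to_matrix(state.quaternion)
    local = body.atoms.coords - body.center_of_mass
    return local @ R.T + state.position, R


class _StackedGridEvaluator:
    """Fused trilinear evaluation of all channels (electrostatic + LJ) at once.

    Valid when every grid in the set shares one lattice (always true for
    sets produced by ``build_gridset``); per-atom channel weights are the
    partial charge for the electrostatic channel and a one-hot category
    indicator for the LJ channels.
    """

    def __init__(self, grids: GridSet, body: MobileBody):
        g0 = grids.electrostatic
        channels = [g0.values]
        for cat in grids.lj:
            g = grids.lj[cat]
            if g.values.shape != g0.values.shape or not np.allclose(g.origin, g0.origin):
                raise ValueError("grids do not share a lattice")
            channels.append(g.values)
        self.values = np.stack(channels)  # (C, nx, ny, nz)
        self.origin = g0.origin
        self.spacing = g0.spacing
        self.dims = np.array(g0.values.shape)
        cats = body.atoms.categories
        if cats is None:
            raise ValueError("mobile body atoms need LJ categories assigned")
        n = len(body.atoms)
        w = np.zeros((n, len(channels)))
        w[:, 0] = body.atoms.charges
        for k, cat in enumerate(grids.lj, start=1):
            w[:, k] = cats == cat
        self.weights = w

    _CORNERS = np.array(
        [[0, 0, 0], [0, 0, 1], [0, 1, 0], [0, 1, 1], [1, 0, 0], [1, 0, 1], [1, 1, 0], [1, 1, 1]]
    )

    def force_energy(self, pts: np.ndarray, inside: np.ndarray):
        """Per-atom forces (n,3) and total energy over the inside-mask atoms."""
        n = len(pts)
        forces = np.zeros((n, 3))
        if not np.any(inside):
            return forces, 0.0
        p = pts[inside]
        W = self.weights[inside]
        rel = (p - self.origin) / self.spacing
        i0 = np.clip(np.floor(rel).astype(int), 0, self.dims - 2)
        f = rel - i0
        off = self._CORNERS
        IX = i0[:, 0][None, :] + off[:, 0:1]
        IY = i0[:, 1][None, :] + off[:, 1:2]
        IZ = i0[:, 2][None, :] + off[:, 2:3]
        c = self.values[:, IX, IY, IZ]  # (C, 8, m)
        cw = np.einsum("ckm,mc->km", c, W)  # channel-weighted corner values

        w1 = np.stack([1 - f[:, 0], f[:, 0]])  # (2, m) per axis
        w2 = np.stack([1 - f[:, 1], f[:, 1]])
        w3 = np.stack([1 - f[:, 2], f[:, 2]])
        dw = np.array([-1.0, 1.0])
        ax, ay, az = off[:, 0], off[:, 1], off[:, 2]
        val = (cw * w1[ax] * w2[ay] * w3[az]).sum(axis=0)
        gx = (cw * dw[ax][:, None] * w2[ay] * w3[az]).sum(axis=0)
        gy = (cw * w1[ax] * dw[ay][:, None] * w3[az]).sum(axis=0)
        gz = (cw * w1[ax] * w2[ay] * dw[az][:, None]).sum(axis=0)
        forces[inside] = np.stack([gx, gy, gz], axis=1) * (-1.0 / self.spacing)
        return forces, float(val.sum())


def _evaluator(grids: GridSet, body: MobileBody) -> _StackedGridEvaluator:
    cache = getattr(grids, "_evaluator_cache", None)
    if cache is not None and cache[0] is body:
        return cache[1]
    ev = _StackedGridEvaluator(grids, body)
    grids._evaluator_cache = (body, ev)
    return ev


def _grid_force_torque(
    state: RigidState, body: MobileBody, grids: Optional[GridSet]
) -> tuple[np.ndarray, np.ndarray, float]:
    """Grid force on the COM, torque about the COM (lab frame), and energy."""
    if grids is None:
        return np.zeros(3), np.zeros(3), 0.0
    pts, _ = _body_points(state, body)
    ev = _evaluator(grids, body)
    lo = ev.origin
    hi = ev.origin + (ev.dims - 1) * ev.spacing
    inside = np.all((pts >= lo) & (pts <= hi), axis=1)
    atom_forces, energy = ev.force_energy(pts, inside)
    force = atom_forces.sum(axis=0)
    r = pts - state.position
    fx, fy, fz = atom_forces[:, 0], atom_forces[:, 1], atom_forces[:, 2]
    rx, ry, rz = r[:, 0], r[:, 1], r[:, 2]
    torque = np.array(
        [
            (ry * fz - rz * fy).sum(),
            (rz * fx - rx * fz).sum(),
            (rx * fy - ry * fx).sum(),
        ]
    )
    return force, torque, energy


def _wall_force(position: np.ndarray, grids: Optional[GridSet], pad: float) -> np.ndarray:
    if grids is None:
        return np.zeros(3)
    lo = grids.electrostatic.origin + pad
    hi = grids.electrostatic.upper - pad
    f = np.zeros(3)
    below = position < lo
    above = position > hi
    f[below] = WALL_K * (lo - position)[below]
    f[above] = -WALL_K * (position - hi)[above]
    return f


def interaction_energy(state: RigidState, body: MobileBody, grids: GridSet) -> float:
    """Total grid interaction energy (kJ/mol) of the body in the given pose."""
    return _grid_force_torque(state, body, grids)[2]


# ---------------------------------------------------------------- propagation

ExternalPotential = Callable[[np.ndarray, float], tuple[float, np.ndarray]]


def bd_step(
    state: RigidState,
    body: MobileBody,
    grids: Optional[GridSet],
    params: BDParams,
    rng: np.random.Generator,
    external: Optional[ExternalPotential] = None,
    _renorm: bool = True,
) -> RigidState:
    """One overdamped step.

    Mobility is 1/friction (fixed by the body's hydrodynamics); the noise
    variance is 2 kBT/friction dt at the propagation temperature, so setting
    ``temperature_K = 0`` recovers deterministic steepest descent.
    ``external`` is a test/steering hook: a callable (COM position, time) ->
    (energy, force on COM).
    """
    dt = params.dt_ns
    kbt = kbt_kj_mol(params.temperature_K) if params.temperature_K > 0 else 0.0

    force, torque, _ = _grid_force_torque(state, body, grids)
    force += _wall_force(state.position, grids, pad=body.radius_A + 1.0)
    if external is not None:
        _, f_ext = external(state.position, state.time_ns)
        force = force + f_ext

    if not np.all(np.isfinite(force)) or not np.all(np.isfinite(torque)):
        raise FloatingPointError("non-finite force or torque in bd_step")

    mob_t = 1.0 / body.friction_trans  # Angstrom^2 / (kJ/mol ns)
    D_t = kbt * mob_t
    dx = mob_t * force * dt
    if kbt > 0:
        dx = dx + np.sqrt(2 * D_t * dt) * rng.standard_normal(3)

    R = _quat_to_matrix(state.quaternion)
    tau_body = R.T @ torque
    mob_r = 1.0 / body.friction_rot
    D_r = kbt * mob_r
    dtheta = mob_r * tau_body * dt
    if kbt > 0:
        dtheta = dtheta + np.sqrt(2 * D_r * dt) * rng.standard_normal(3)

    q = _quat_multiply(state.quaternion, _rotvec_to_quat(dtheta))
    if _renorm:
        q = q / np.linalg.norm(q)
    new = RigidState.__new__(RigidState)
    new.position = state.position + dx
    new.quaternion = q
    new.time_ns = state.time_ns + dt
    return new


def run_trajectory(
    body: MobileBody,
    grids: Optional[GridSet],
    params: BDParams,
    start: RigidState,
    external: Optional[ExternalPotential] = None,
) -> Trajectory:
    """Propagate one replica, recording frames every ``record_every_ns``.

    The recorded series always includes the start pose and runs for
    ``duration_ns``; identical parameters and seed give identical frames.
    """
    rng = np.random.default_rng(params.seed)
    n_steps = int(round(params.duration_ns / params.dt_ns))
    stride = max(1, int(round(params.record_every_ns / params.dt_ns)))

    times = [start.time_ns]
    positions = [start.position.copy()]
    quats = [start.quaternion.copy()]
    energies = [interaction_energy(start, body, grids) if grids is not None else 0.0]

    state = start
    for i in range(1, n_steps + 1):
        state = bd_step(state, body, grids, params, rng, external)
        if i % stride == 0 or i == n_steps:
            times.append(state.time_ns)
            positions.append(state.position.copy())
            quats.append(state.quaternion.copy())
            energies.append(
                interaction_energy(state, body, grids) if grids is not None else 0.0
            )
    return Trajectory(
        np.asarray(times),
        np.asarray(positions),
        np.asarray(quats),
        np.asarray(energies),
        params,
        params.seed,
    )


def steered_pull(
    body: MobileBody,
    grids: GridSet,
    path_start,
    path_end,
    velocity_A_per_ns: float = 0.05,
    spring_k: float = 5.0,
    params: BDParams = BDParams(),
    site_point=None,
    record_every_ns: float | None = None,
) -> pd.DataFrame:
    """Drag the COM along a path with a moving harmonic restraint.

    The restraint center moves from ``path_start`` to ``path_end`` at
    constant velocity; orientation is free.  Returns the interaction-energy
    profile vs the donor-acceptor distance (COM to ``site_point``, default
    the path end).
    """
    path_start = np.asarray(path_start, dtype=float)
    path_end = np.asarray(path_end, dtype=float)
    site = path_end if site_point is None else np.asarray(site_point, dtype=float)
    length = float(np.linalg.norm(path_end - path_start))
    direction = (path_end - path_start) / length
    duration = length / velocity_A_per_ns
    rec = params.record_every_ns if record_every_ns is None else record_every_ns

    def restraint(pos: np.ndarray, t: float) -> tuple[float, np.ndarray]:
        center = path_start + direction * min(velocity_A_per_ns * t, length)
        d = pos - center
        return 0.5 * spring_k * float(d @ d), -spring_k * d

    rng = np.random.default_rng(params.seed)
    n_steps = int(round(duration / params.dt_ns))
    stride = max(1, int(round(rec / params.dt_ns)))
    state = RigidState(position=path_start.copy())
    rows = []
    for i in range(n_steps + 1):
        if i % stride == 0 or i == n_steps:
            rows.append(
                {
                    "time_ns": state.time_ns,
                    "reaction_coordinate_A": float(np.linalg.norm(state.position - site)),
                    "restraint_position_A": float(
                        np.linalg.norm(
                            path_start
                            + direction * min(velocity_A_per_ns * state.time_ns, length)
                            - site
                        )
                    ),
                    "energy_kJ_mol": interaction_energy(state, body, grids),
                }
            )
        if i < n_steps:
            state = bd_step(state, body, grids, params, rng, external=restraint)
    return pd.DataFrame(rows)
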