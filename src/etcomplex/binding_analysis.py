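"""Contact kinetics, binding-pose clustering and occupancy-based affinity.

Trajectories are reduced to a per-frame minimum heavy-atom distance between
the mobile protein and the receptor; a hysteretic two-threshold rule (bound
below 7 A, released above 16 A) converts that into bound intervals without
flicker.  Bound poses are clustered by single linkage on COM positions and
labelled proximal (electron-transfer site) or distal (peripheral
light-harvesting ring) from receptor annotations.  Site affinity is
estimated from single-molecule occupancy with an explicit simulation-volume
correction: KD = (1-p)/p * 1/(NA V).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.signal import find_peaks
from scipy.spatial import cKDTree

from .constants import N_AVOGADRO
from .rigid_body_bd import Trajectory, _quat_to_matrix
from .structure_props import AtomSet, MobileBody

__all__ = [
    "ContactSeries",
    "PoseCluster",
    "KDEstimate",
    "hysteretic_bound_flags",
    "contact_series",
    "cluster_poses",
    "occupancy_kd",
    "detect_states",
]


@dataclass
class ContactSeries:
    """Per-frame contact record of one replica."""

    times_ns: np.ndarray
    min_distance_A: np.ndarray
    bound: np.ndarray
    intervals_ns: list[tuple[float, float]]

    @property
    def bound_fraction(self) -> float:
        return float(np.mean(self.bound)) if len(self.bound) else 0.0


@dataclass
class PoseCluster:
    """One cluster of bound poses."""

    member_indices: np.ndarray
    representative: np.ndarray  # COM position of the medoid frame
    occupancy: float  # fraction of all frames (bound and unbound)
    site: str  # proximal | distal | other
    mean_interface_A: float


@dataclass
class KDEstimate:
    """Occupancy-based dissociation constant for one site."""

    site: str
    p_bound: float
    kd_M: float
    ci_M: tuple[float, float]
    detected: bool = True


def hysteretic_bound_flags(
    min_distance_A, on_A: float = 7.0, off_A: float = 16.0
) -> np.ndarray:
    """Two-threshold bound/unbound state machine over a distance sequence.

    The state switches on only when the distance falls below ``on_A`` and
    off only when it rises above ``off_A``; with on == off this reduces to
    simple thresholding.
    """
    d = np.asarray(min_distance_A, dtype=float)
    flags = np.zeros(len(d), dtype=bool)
    bound = False
    for i, x in enumerate(d):
        if not bound and x < on_A:
            bound = True
        elif bound and x > off_A:
            bound = False
        flags[i] = bound
    return flags


def _intervals(times: np.ndarray, bound: np.ndarray) -> list[tuple[float, float]]:
    out: list[tuple[float, float]] = []
    start = None
    for t, b in zip(times, bound):
        if b and start is None:
            start = t
        elif not b and start is not None:
            out.append((start, t))
            start = None
    if start is not None:
        out.append((start, float(times[-1])))
    return out


def frame_min_distances(
    traj: Trajectory, body: MobileBody, receptor: AtomSet
) -> np.ndarray:
    """Minimum heavy-atom distance body-receptor for every recorded frame."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    rec_tree = cKDTree(receptor.coords[receptor.heavy_mask])
    local = body.atoms.coords[body.atoms.heavy_mask] - body.center_of_mass
    dmin = np.empty(len(traj))
    for i in range(len(traj)):
        R = _quat_to_matrix(traj.quaternions[i])
        pts = local @ R.T + traj.positions[i]
        dmin[i] = rec_tree.query(pts, k=1)[0].min()
    return dmin


def contact_series(
    traj: Trajectory,
    body: MobileBody,
    receptor: AtomSet,
    on_A: float = 7.0,
    off_A: float = 16.0,
) -> ContactSeries:
    """Hysteretic contact record of one trajectory (7/16 A rule by default)."""
    dmin = frame_min_distances(traj, body, receptor)
    bound = hysteretic_bound_flags(dmin, on_A, off_A)
    return ContactSeries(traj.times_ns, dmin, bound, _intervals(traj.times_ns, bound))


def cluster_poses(
    bound_positions,
    interface_distances_A,
    n_total_frames: int,
    linkage_A: float = 8.0,
    site_annotations: Optional[dict] = None,
    max_interface_A: float = 10.0,
) -> list[PoseCluster]:
    """Single-linkage clustering of bound-frame COM positions.

    ``site_annotations`` maps labels (e.g. ``proximal``/``distal``) to
    marker coordinates; a cluster takes the label of the marker nearest its
    representative pose.  Clusters whose mean interface distance exceeds
    ``max_interface_A`` are discarded.
    """
    pos = np.atleast_2d(np.asarray(bound_positions, dtype=float))
    iface = np.asarray(interface_distances_A, dtype=float)
    if len(pos) == 0:
        return []
    if len(pos) == 1:
        labels = np.array([1])
    else:
        labels = fcluster(linkage(pos, method="single"), t=linkage_A, criterion="distance")

    clusters: list[PoseCluster] = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        members = pos[idx]
        center = members.mean(axis=0)
        medoid = members[np.argmin(np.linalg.norm(members - center, axis=1))]
        mean_iface = float(iface[idx].mean())
        if mean_iface > max_interface_A:
            continue
        site = "other"
        if site_annotations:
            site = min(
                site_annotations,
                key=lambda s: np.linalg.norm(medoid - np.asarray(site_annotations[s])),
            )
        clusters.append(
            PoseCluster(
                member_indices=idx,
                representative=medoid,
                occupancy=len(idx) / n_total_frames,
                site=str(site),
                mean_interface_A=mean_iface,
            )
        )
    clusters.sort(key=lambda c: -c.occupancy)
    return clusters


def occupancy_kd(
    per_replica_bound_fraction,
    simulation_volume_A3: float,
    site: str = "all",
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> KDEstimate:
    """Dissociation constant from single-molecule occupancy.

    One molecule in volume V corresponds to concentration c0 = 1/(NA V);
    KD = (1 - p)/p * c0.  The CI is a percentile bootstrap over replicas.
    """
    fracs = np.asarray(per_replica_bound_fraction, dtype=float)
    if len(fracs) < 1:
        raise ValueError("need at least one replica")
    c0 = 1.0 / (N_AVOGADRO * simulation_volume_A3 * 1e-27)  # mol/L
    p = float(fracs.mean())
    if p <= 0:
        return KDEstimate(site, 0.0, float("inf"), (float("inf"), float("inf")), detected=False)

    def kd_of(pb: float) -> float:
        return float("inf") if pb <= 0 else (1.0 - pb) / pb * c0 if pb < 1 else 0.0

    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_bootstrap):
        boots.append(kd_of(float(rng.choice(fracs, size=len(fracs)).mean())))
    lo, hi = np.percentile([b for b in boots], [2.5, 97.5])
    return KDEstimate(site, p, kd_of(p), (float(lo), float(hi)))


def detect_states(
    profile: pd.DataFrame,
    smoothing_window: int = 5,
    prominence_kJ_mol: float = 1.0,
    coordinate_col: str = "reaction_coordinate_A",
    energy_col: str = "energy_kJ_mol",
) -> list[tuple[float, float]]:
    """Intermediate states on a steered-pulling energy profile.

    Moving-average smoothing followed by local-minimum detection with a
    prominence threshold on the interaction-energy magnitude; returns
    (position, depth) pairs ordered along the reaction coordinate.
    """
    if len(profile) < 20:
        raise ValueError("profile needs at least 20 points")
    order = np.argsort(profile[coordinate_col].to_numpy())
    x = profile[coordinate_col].to_numpy()[order]
    e = profile[energy_col].to_numpy()[order]
    w = max(1, int(smoothing_window))
    padded = np.pad(e, (w // 2, w - 1 - w // 2), mode="edge")
    sm = np.convolve(padded, np.ones(w) / w, mode="valid")
    peaks, props = find_peaks(-sm, prominence=prominence_kJ_mol)
    states = [(float(x[i]), float(sm[i])) for i in peaks]
    states.sort(key=lambda s: s[0])
    return states
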