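#!/usr/bin/env python
"""Brownian-dynamics binding study on the two-site toy receptor.

Builds the bead receptor with a strong (proximal / electron-transfer) and a
weak (distal / antenna-ring) electrostatic well, precomputes smoothed 1 A
grids at 10 mM ionic strength, runs six rigid-body BD replicas from an
unbound start, and reduces them to hysteretic (7/16 A) contact kinetics,
binding-pose clusters and occupancy-based KD per site.  Writes
results/binding_report.json.
"""

import json
from pathlib import Path

import numpy as np

from etcomplex.binding_analysis import cluster_poses, contact_series, occupancy_kd
from etcomplex.grid_potentials import assign_lj_categories, build_gridset
from etcomplex.rigid_body_bd import BDParams, RigidState, run_trajectory
from etcomplex.structure_props import build_mobile_body, write_structure
from etcomplex.toys import bead_body, two_site_receptor

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    receptor, annotations = two_site_receptor(
        proximal_charge_e=-5.0, distal_charge_e=-2.0, site_separation_A=36.0
    )
    grids = build_gridset(receptor, ionic_strength_mM=10.0, spacing=1.0, margin_A=28.0)
    atoms = bead_body()
    assign_lj_categories(atoms)
    body = build_mobile_body(atoms)
    OUT.mkdir(exist_ok=True)
    write_structure(receptor, OUT / "toy_receptor.pdb")

    pos_all, iface_all, prox_fracs, dist_fracs = [], [], [], []
    n_frames = 0
    for r in range(6):
        params = BDParams(duration_ns=4.0, record_every_ns=0.02, seed=100 + r)
        traj = run_trajectory(body, grids, params, RigidState(position=np.array([0.0, 0.0, 16.0])))
        cs = contact_series(traj, body, receptor)
        in_contact = cs.bound & (cs.min_distance_A < 7.0)
        n_frames += len(cs.bound)
        pos_all.append(traj.positions[in_contact])
        iface_all.append(cs.min_distance_A[in_contact])
        prox = traj.positions[:, 0] < 0
        prox_fracs.append(float(np.mean(cs.bound & prox)))
        dist_fracs.append(float(np.mean(cs.bound & ~prox)))
        print(
            f"replica {r}: bound fraction {cs.bound_fraction:.2f}, "
            f"{len(cs.intervals_ns)} bound interval(s)"
        )

    clusters = cluster_poses(
        np.concatenate(pos_all), np.concatenate(iface_all), n_frames,
        site_annotations=annotations,
    )
    volume = float(np.prod(grids.electrostatic.upper - grids.electrostatic.origin))
    kd_prox = occupancy_kd(prox_fracs, volume, site="proximal", seed=1)
    kd_dist = occupancy_kd(dist_fracs, volume, site="distal", seed=1)

    report = {
        "simulation_volume_A3": volume,
        "clusters": [
            {
                "site": c.site,
                "n_poses": int(len(c.member_indices)),
                "representative_A": [round(float(v), 1) for v in c.representative],
                "mean_interface_A": round(c.mean_interface_A, 2),
            }
            for c in clusters
        ],
        "kd": {
            est.site: {"p_bound": est.p_bound, "kd_M": est.kd_M, "ci_M": list(est.ci_M)}
            for est in (kd_prox, kd_dist)
        },
    }
    (OUT / "binding_report.json").write_text(json.dumps(report, indent=2))
    print(f"\nKD proximal {kd_prox.kd_M:.2e} M  <  KD distal {kd_dist.kd_M:.2e} M")
    print(f"report written to {OUT / 'binding_report.json'}")


if __name__ == "__main__":
    main()
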