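"""Readers and writers for the package's plain-text artifact formats.

Curve bundles are a directory with a long-format ``curves.tsv``, the
generator ``truth.tsv`` and a ``meta.yaml`` sidecar holding the condition,
acquisition parameters and seed, so any bundle can be re-analyzed or
regenerated bit-identically.  Events, contacts and trajectories are TSV;
grids are OpenDX (see :mod:`etcomplex.grid_potentials`).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .rigid_body_bd import BDParams, Trajectory
from .synthetic_smfs import AcquisitionParams, ConditionPreset, CurveBundle, ForceCurve

__all__ = [
    "write_bundle",
    "read_bundle",
    "write_events",
    "read_events",
    "write_trajectory",
    "read_trajectory",
    "config_hash",
]


def config_hash(config: dict) -> str:
    """Stable short hash of a resolved run configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_bundle(bundle: CurveBundle, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for c in bundle.curves:
        rows.append(
            pd.DataFrame(
                {
                    "curve_id": c.curve_id,
                    "segment": c.segment,
                    "separation_nm": c.separation_nm,
                    "force_pN": c.force_pN,
                }
            )
        )
    frame = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["curve_id", "segment", "separation_nm", "force_pN"])
    )
    frame.to_csv(out / "curves.tsv", sep="\t", index=False, float_format="%.6g")
    bundle.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    meta = {
        "preset": dataclasses.asdict(bundle.preset),
        "acquisition": dataclasses.asdict(bundle.params),
        "seed": int(bundle.seed),
        "n_complexes": int(bundle.n_complexes),
    }
    meta["preset"]["offset_range_nm"] = list(bundle.preset.offset_range_nm)
    with open(out / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return out


def read_bundle(in_dir) -> CurveBundle:
    src = Path(in_dir)
    with open(src / "meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    meta["preset"]["offset_range_nm"] = tuple(meta["preset"]["offset_range_nm"])
    preset = ConditionPreset(**meta["preset"])
    params = AcquisitionParams(**meta["acquisition"])
    frame = pd.read_csv(src / "curves.tsv", sep="\t")
    truth = pd.read_csv(src / "truth.tsv", sep="\t")
    curves = []
    if len(frame):
        for cid, grp in frame.groupby("curve_id", sort=False):
            curves.append(
                ForceCurve(
                    grp["separation_nm"].to_numpy(),
                    grp["force_pN"].to_numpy(),
                    segment=str(grp["segment"].iloc[0]),
                    curve_id=str(cid),
                )
            )
    return CurveBundle(
        curves, truth, preset, params, int(meta["seed"]), int(meta["n_complexes"])
    )


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_trajectory(traj: Trajectory, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traj.to_frame().to_csv(out / "frames.tsv", sep="\t", index=False)
    with open(out / "meta.yaml", "w") as fh:
        yaml.safe_dump(
            {"params": dataclasses.asdict(traj.params), "seed": int(traj.seed)}, fh
        )
    return out


def read_trajectory(in_dir) -> Trajectory:
    src = Path(in_dir)
    frames = pd.read_csv(src / "frames.tsv", sep="\t")
    with open(src / "meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    params = BDParams(**meta["params"])
    return Trajectory(
        frames["time_ns"].to_numpy(),
        frames[["x", "y", "z"]].to_numpy(),
        frames[["qw", "qx", "qy", "qz"]].to_numpy(),
        frames["energy_kJ_mol"].to_numpy(),
        params,
        int(meta["seed"]),
    )
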