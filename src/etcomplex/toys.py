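"""Programmatically generated bead-model "proteins" (synthetic fixtures).

Small synthetic structures used by the test suite and the desk-scale
analyses in place of the full atomic models: a compact charged bead body
standing in for the soluble cytochrome, and flat bead receptors with one or
two engineered electrostatic binding wells standing in for the
reaction-center / light-harvesting complex.  They are valid PDB-writable
AtomSets, so the whole pipeline (structure -> grids -> BD -> binding
analysis) runs on them unchanged.
"""

from __future__ import annotations

import numpy as np

from .structure_props import AtomSet, load_atom_params

__all__ = ["bead_body", "two_site_receptor", "single_well_receptor"]


def _atomset(coords, elements, charges) -> AtomSet:
    table = load_atom_params()
    masses = [
        float(table.loc[e, "mass_amu"]) if e in table.index else 12.0 for e in elements
    ]
    return AtomSet(
        coords=np.asarray(coords, dtype=float),
        elements=np.asarray(elements, dtype=object),
        charges=np.asarray(charges, dtype=float),
        masses=np.asarray(masses, dtype=float),
    )


def bead_body(radius_A: float = 3.0, charge_e: float = 2.0) -> AtomSet:
    """Compact 7-bead mobile body: one central N bead carrying the charge
    plus an octahedral carbon shell.  Mimics a small basic ET protein."""
    coords = [[0.0, 0.0, 0.0]]
    elements = ["N"]
    charges = [charge_e]
    for axis in range(3):
        for s in (-1.0, 1.0):
            p = [0.0, 0.0, 0.0]
            p[axis] = s * radius_A
            coords.append(p)
            elements.append("C")
            charges.append(0.0)
    return _atomset(coords, elements, charges)


def _plate(nx: int, ny: int, spacing: float, z: float = 0.0):
    xs = (np.arange(nx) - (nx - 1) / 2) * spacing
    ys = (np.arange(ny) - (ny - 1) / 2) * spacing
    pts = [[x, y, z] for x in xs for y in ys]
    return pts


def _site_cluster(center, charge_total: float, element: str = "O"):
    """Four charged beads in a shallow pocket around ``center``."""
    c = np.asarray(center, dtype=float)
    offsets = np.array(
        [[1.5, 1.5, 0.0], [-1.5, 1.5, 0.0], [1.5, -1.5, 0.0], [-1.5, -1.5, 0.0]]
    )
    coords = (c + offsets).tolist()
    q = charge_total / 4.0
    return coords, [element] * 4, [q] * 4


def two_site_receptor(
    proximal_charge_e: float = -6.0,
    distal_charge_e: float = -2.0,
    site_separation_A: float = 28.0,
    plate_spacing_A: float = 4.0,
) -> tuple[AtomSet, dict[str, np.ndarray]]:
    """Bead receptor with two charged surface wells on separate pads.

    The strongly charged "proximal" well marks the electron-transfer site,
    the weakly charged "distal" well the peripheral ring region.  The pads
    are separated by a surface gap wider than the contact threshold, so a
    particle sliding from one site to the other must leave contact - as
    when crossing from the reaction-center core to the antenna ring.
    Returns the AtomSet plus site annotations (markers above each well).
    """
    half = site_separation_A / 2.0
    coords: list = []
    elements: list = []
    charges: list = []
    for center, q in (([-half, 0.0, 2.0], proximal_charge_e), ([half, 0.0, 2.0], distal_charge_e)):
        pad = np.asarray(_plate(5, 5, plate_spacing_A, z=0.0)) + np.array([center[0], 0.0, 0.0])
        coords += pad.tolist()
        elements += ["C"] * len(pad)
        charges += [0.0] * len(pad)
        cc, ee, qq = _site_cluster(center, q)
        coords += cc
        elements += ee
        charges += qq

    annotations = {
        "proximal": np.array([-half, 0.0, 6.0]),
        "distal": np.array([half, 0.0, 6.0]),
    }
    return _atomset(coords, elements, charges), annotations


def single_well_receptor(
    well_charge_e: float = -4.0, plate_spacing_A: float = 4.0
) -> tuple[AtomSet, dict[str, np.ndarray]]:
    """Flat bead receptor with a single central charged well."""
    coords = _plate(6, 6, plate_spacing_A, z=0.0)
    elements = ["C"] * len(coords)
    charges = [0.0] * len(coords)
    cc, ee, qq = _site_cluster([0.0, 0.0, 2.0], well_charge_e)
    coords += cc
    elements += ee
    charges += qq
    return _atomset(coords, elements, charges), {"well": np.array([0.0, 0.0, 6.0])}
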