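"""Independent reference computations used as test oracles."""

import numpy as np

from etcomplex.constants import COULOMB_KJ_A, WATER_DIELECTRIC, debye_length_A
from etcomplex.structure_props import AtomSet, load_atom_params


def pairwise_reference_energy(
    body_atoms: AtomSet,
    body_categories,
    category_params,
    receptor: AtomSet,
    body_positions: np.ndarray,
    ionic_strength_mM: float,
    lj_cap_kJ_mol: float = 100.0,
) -> float:
    """Direct double-sum Debye-Hueckel + 12-6 LJ energy (no grids).

    Mirrors the physical model but not the implementation: explicit pair
    loops, per-receptor-atom element parameters, per-body-atom category
    parameters.  The per-body-atom LJ sum is capped like the grid values.
    """
    table = load_atom_params()
    lam = debye_length_A(ionic_strength_mM)
    pref = COULOMB_KJ_A / WATER_DIELECTRIC
    total = 0.0
    for i in range(len(body_positions)):
        p = body_positions[i]
        q = body_atoms.charges[i]
        elec = 0.0
        lj = 0.0
        for j in range(len(receptor)):
            r = float(np.linalg.norm(p - receptor.coords[j]))
            qj = receptor.charges[j]
            if q != 0.0 and qj != 0.0:
                elec += pref * q * qj * np.exp(-r / lam) / r
            el = str(receptor.elements[j]).upper()
            row = table.loc[el] if el in table.index else table.loc["C"]
            cat = body_categories[i]
            rmin = category_params.rmin_half_A[cat] + float(row["rmin_half_A"])
            eps = np.sqrt(category_params.epsilon_kJ_mol[cat] * float(row["epsilon_kJ_mol"]))
            sr6 = (rmin / r) ** 6
            lj += eps * (sr6**2 - 2 * sr6)
        total += elec + min(lj, lj_cap_kJ_mol)
    return total


def reference_hysteresis(distances, on, off):
    """Plain state-machine re-implementation of the two-threshold contact rule."""
    out = []
    bound = False
    for d in distances:
        if bound:
            if d > off:
                bound = False
        else:
            if d < on:
                bound = True
        out.append(bound)
    return out
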