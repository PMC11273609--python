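"""Rigid-body mechanical and hydrodynamic properties of the mobile protein.

Mass, center of mass and the inertia tensor come directly from the atomic
coordinates.  Diffusion coefficients use a Kirkwood bead approximation:
solvent-exposed atoms become Stokes beads and the translational diffusion
coefficient follows from the Kirkwood double sum, with the rotational
coefficient taken from the hydrodynamically equivalent sphere.  Friction is
obtained from diffusion through the Stokes-Einstein relation, so the
fluctuation-dissipation balance used by the Brownian propagator holds by
construction.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .constants import WATER_VISCOSITY, kbt_kj_mol

__all__ = [
    "AtomSet",
    "MobileBody",
    "load_atom_params",
    "load_structure",
    "write_structure",
    "mass_and_inertia",
    "diffusion_coefficients",
    "friction_from_diffusion",
    "build_mobile_body",
]

_KB_SI = 1.380649e-23
#: m^2/s -> Angstrom^2/ns
_M2S_TO_A2NS = 1e11

#: default hydrodynamic bead radius: atomic radius + hydration shell (Angstrom)
DEFAULT_BEAD_RADIUS_A = 1.2 + 1.1


@dataclass
class AtomSet:
    """Atoms of one rigid unit: coordinates (Angstrom), elements, charges (e),
    masses (amu) and Lennard-Jones category ids ('H', 'ON', 'CS')."""

    coords: np.ndarray
    elements: np.ndarray
    charges: np.ndarray
    masses: np.ndarray
    categories: np.ndarray | None = None
    names: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        n = len(self.coords)
        if n < 1:
            raise ValueError("AtomSet needs at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        self.elements = np.asarray(self.elements, dtype=object)
        self.charges = np.asarray(self.charges, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.names is None:
            self.names = np.asarray([str(e) for e in self.elements], dtype=object)

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.asarray([e.upper() != "H" for e in self.elements])


@dataclass
class MobileBody:
    """Rigid-body model of the mobile protein (the soluble cytochrome)."""

    atoms: AtomSet
    mass: float
    center_of_mass: np.ndarray
    inertia_tensor: np.ndarray
    D_trans: np.ndarray  # Angstrom^2/ns, diagonal (principal frame)
    D_rot: np.ndarray  # rad^2/ns, diagonal
    friction_trans: np.ndarray  # kJ/mol ns / Angstrom^2
    friction_rot: np.ndarray  # kJ/mol ns / rad^2
    temperature_K: float = 300.0

    @property
    def radius_A(self) -> float:
        """Largest atom distance from the COM (cached)."""
        r = getattr(self, "_radius_A", None)
        if r is None:
            r = float(
                np.linalg.norm(self.atoms.coords - self.center_of_mass, axis=1).max()
            )
            self._radius_A = r
        return r


def load_atom_params() -> pd.DataFrame:
    """Packaged per-element parameter table (mass, default charge, LJ)."""
    ref = importlib.resources.files("etcomplex") / "data" / "atom_params.tsv"
    with importlib.resources.as_file(ref) as path:
        tab = pd.read_csv(path, sep="\t", comment="#")
    return tab.set_index("element")


_KNOWN_ELEMENTS = {"H", "C", "N", "O", "S", "P", "FE", "ZN", "MG", "MN", "CU", "CA", "NA", "K", "CL"}


def _infer_element(atom_name: str, element_field: str) -> str:
    field = element_field.strip().upper()
    if field in _KNOWN_ELEMENTS:
        return field
    name = atom_name.strip()
    # two-letter metals are unambiguous; CA/NA/... collide with protein atom names
    if name[:2].upper() in {"FE", "ZN", "MG", "MN", "CU"}:
        return name[:2].upper()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


def load_structure(path, charges: dict[str, float] | None = None) -> AtomSet:
    """Read a PDB-format file (ATOM and HETATM records) into an AtomSet.

    Partial charges come from an optional ``charges`` mapping (atom name ->
    charge); otherwise the per-element default from the packaged table.
    Malformed coordinate records raise a parse error naming the lines.
    """
    params = load_atom_params()
    coords, elements, names, qs, masses = [], [], [], [], []
    bad_lines: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            try:
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError:
                bad_lines.append(lineno)
                continue
            name = line[12:16]
            element = _infer_element(name, line[76:78] if len(line) >= 78 else "")
            coords.append((x, y, z))
            elements.append(element)
            names.append(name.strip())
            row = params.loc[element] if element in params.index else None
            default_q = float(row["charge_default_e"]) if row is not None else 0.0
            qs.append(charges.get(name.strip(), default_q) if charges else default_q)
            masses.append(float(row["mass_amu"]) if row is not None else 12.0)
    if bad_lines:
        raise ValueError(f"malformed PDB coordinate records at lines {bad_lines}")
    if not coords:
        raise ValueError(f"no ATOM/HETATM records found in {path}")
    return AtomSet(
        coords=np.asarray(coords),
        elements=np.asarray(elements, dtype=object),
        charges=np.asarray(qs),
        masses=np.asarray(masses),
        names=np.asarray(names, dtype=object),
    )


def write_structure(atoms: AtomSet, path) -> None:
    """Write an AtomSet as a minimal PDB file (3-decimal coordinates)."""
    with open(path, "w") as fh:
        for i in range(len(atoms)):
            x, y, z = atoms.coords[i]
            el = str(atoms.elements[i])[:2].upper()
            name = str(atoms.names[i])[:4]
            fh.write(
                f"ATOM  {i + 1:5d} {name:<4s} BEA A{(i % 9999) + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}\n"
            )
        fh.write("END\n")


def mass_and_inertia(atoms: AtomSet) -> tuple[float, np.ndarray, np.ndarray]:
    """Total mass (amu), center of mass and inertia tensor (amu A^2) about the COM."""
    m = atoms.masses
    total = float(m.sum())
    if total <= 0:
        raise ValueError("zero total mass")
    com = (m[:, None] * atoms.coords).sum(axis=0) / total
    r = atoms.coords - com
    r2 = (r**2).sum(axis=1)
    inertia = np.eye(3) * float((m * r2).sum()) - np.einsum("a,ai,aj->ij", m, r, r)
    return total, com, inertia


def surface_atom_mask(
    atoms: AtomSet,
    probe_radius_A: float = 1.4,
    grid_spacing_A: float = 1.0,
    atom_radius_A: float = 1.2 + 1.1,
) -> np.ndarray:
    """Solvent-exposed atoms by a rolling-probe occupancy test on a grid.

    Grid points closer than (atom radius + probe) to any atom center are
    occupied; an atom is surface if a solvent point lies within reach of its
    probe-inflated radius.  Single-atom inputs are trivially surface.
    """
    coords = atoms.coords
    if len(coords) == 1:
        return np.ones(1, dtype=bool)
    pad = atom_radius_A + 2 * probe_radius_A + grid_spacing_A
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    axes = [np.arange(lo[k], hi[k] + grid_spacing_A, grid_spacing_A) for k in range(3)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    tree = cKDTree(coords)
    d_near, _ = tree.query(pts, k=1)
    solvent = pts[d_near > atom_radius_A + probe_radius_A]
    if len(solvent) == 0:
        return np.ones(len(coords), dtype=bool)
    d_solv, _ = cKDTree(solvent).query(coords, k=1)
    reach = atom_radius_A + probe_radius_A + grid_spacing_A
    return d_solv <= reach


def diffusion_coefficients(
    atoms: AtomSet,
    temperature_K: float = 300.0,
    viscosity_Pa_s: float = WATER_VISCOSITY,
    bead_radius_A: float = DEFAULT_BEAD_RADIUS_A,
) -> tuple[np.ndarray, np.ndarray]:
    """Kirkwood bead-model diffusion coefficients.

    Surface atoms become Stokes beads of ``bead_radius_A``; the translational
    coefficient is the Kirkwood double sum

        D_t = kBT / (6 pi eta a N) + kBT / (8 pi eta N^2) * sum_{i!=j} 1/r_ij,

    reported isotropically (Angstrom^2/ns).  The rotational coefficient uses
    the sphere of equivalent translational mobility: D_r = kBT/(8 pi eta
    a_eq^3) (rad^2/ns).
    """
    mask = surface_atom_mask(atoms)
    beads = atoms.coords[mask] * 1e-10  # m
    n = len(beads)
    a = bead_radius_A * 1e-10
    kbt = _KB_SI * temperature_K
    eta = viscosity_Pa_s
    D = kbt / (6 * np.pi * eta * a * n)
    if n > 1:
        diff = beads[:, None, :] - beads[None, :, :]
        r = np.sqrt((diff**2).sum(axis=-1))
        inv = np.where(np.eye(n, dtype=bool), 0.0, 1.0 / np.maximum(r, 2 * a * 1e-6))
        D += kbt / (8 * np.pi * eta * n**2) * inv.sum()
    a_eq = kbt / (6 * np.pi * eta * D)
    D_rot = kbt / (8 * np.pi * eta * a_eq**3)
    return (
        np.full(3, D * _M2S_TO_A2NS),
        np.full(3, D_rot * 1e-9),
    )


def friction_from_diffusion(D, temperature_K: float = 300.0):
    """Stokes-Einstein: friction = kBT / D, componentwise (kBT in kJ/mol)."""
    D = np.asarray(D, dtype=float)
    if np.any(D <= 0):
        raise ValueError("diffusion coefficients must be positive")
    out = kbt_kj_mol(temperature_K) / D
    return float(out) if out.ndim == 0 else out


def build_mobile_body(
    atoms: AtomSet,
    temperature_K: float = 300.0,
    viscosity_Pa_s: float = WATER_VISCOSITY,
    bead_radius_A: float = DEFAULT_BEAD_RADIUS_A,
) -> MobileBody:
    """Assemble the full rigid-body model used by the Brownian propagator."""
    mass, com, inertia = mass_and_inertia(atoms)
    D_t, D_r = diffusion_coefficients(atoms, temperature_K, viscosity_Pa_s, bead_radius_A)
    return MobileBody(
        atoms=atoms,
        mass=mass,
        center_of_mass=com,
        inertia_tensor=inertia,
        D_trans=D_t,
        D_rot=D_r,
        friction_trans=friction_from_diffusion(D_t, temperature_K),
        friction_rot=friction_from_diffusion(D_r, temperature_K),
        temperature_K=temperature_K,
    )
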