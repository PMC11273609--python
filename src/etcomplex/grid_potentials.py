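"""Precomputed receptor potential grids for Brownian-dynamics force evaluation.

The fixed receptor is summarized by one screened-electrostatic grid (energy
of a unit positive probe charge, Debye-Hueckel screening, relative
dielectric 78.5) and one Lennard-Jones grid per mobile-atom category.  The
mobile protein's atoms are clustered into three LJ categories - H (all
hydrogens), ON (oxygen + nitrogen), CS (carbon + sulfur) - each carrying the
average Rmin and epsilon of its members.  Grids are built at fixed spacing
(1 Angstrom by default), smoothed by a 1 Angstrom Gaussian filter, and
evaluated by trilinear interpolation with analytic gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .constants import COULOMB_KJ_A, WATER_DIELECTRIC, debye_length_A
from .structure_props import AtomSet, load_atom_params

__all__ = [
    "PotentialGrid",
    "GridSet",
    "LJCategoryParams",
    "assign_lj_categories",
    "electrostatic_grid",
    "lj_grid",
    "build_gridset",
    "smooth_grid",
    "interpolate",
    "write_gridset",
    "read_gridset",
]

LJ_CATEGORIES = ("H", "ON", "CS")
_ELEMENT_TO_CATEGORY = {"H": "H", "O": "ON", "N": "ON", "C": "CS", "S": "CS"}

#: default ceiling for LJ grid values in clash regions, kJ/mol
DEFAULT_LJ_CAP_KJ_MOL = 100.0


@dataclass(frozen=True)
class LJCategoryParams:
    """Per-category averaged Lennard-Jones parameters.

    ``rmin_half_A`` follows the CHARMM convention: the pair minimum distance
    is rmin_half_i + rmin_half_j (Lorentz-Berthelot), and pair epsilon is the
    geometric mean.
    """

    rmin_half_A: dict[str, float]
    epsilon_kJ_mol: dict[str, float]

    def pair(self, cat_a: str, rmin_half_b: float, eps_b: float) -> tuple[float, float]:
        rmin = self.rmin_half_A[cat_a] + rmin_half_b
        eps = float(np.sqrt(self.epsilon_kJ_mol[cat_a] * eps_b))
        return rmin, eps


@dataclass
class PotentialGrid:
    """A scalar field on a regular grid with fixed spacing (Angstrom)."""

    origin: np.ndarray
    spacing: float
    values: np.ndarray  # shape = dims
    kind: str  # electrostatic | LJ_H | LJ_ON | LJ_CS

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if min(self.values.shape) < 2:
            raise ValueError("grids need at least 2 nodes per axis")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def upper(self) -> np.ndarray:
        return self.origin + (np.array(self.dims) - 1) * self.spacing

    def axes(self) -> list[np.ndarray]:
        return [
            self.origin[k] + self.spacing * np.arange(self.dims[k]) for k in range(3)
        ]


@dataclass
class GridSet:
    """Electrostatic plus per-category LJ grids of one receptor."""

    electrostatic: PotentialGrid
    lj: dict[str, PotentialGrid]
    category_params: LJCategoryParams


def assign_lj_categories(atoms: AtomSet) -> tuple[AtomSet, LJCategoryParams]:
    """Cluster atoms into the three LJ categories and average their parameters.

    H -> H; O, N -> ON; C, S -> CS.  Unknown elements fall back to the CS
    category with a warning.  Category Rmin/2 and epsilon are arithmetic
    means over the member atoms present in the input.
    """
    import warnings

    table = load_atom_params()
    cats = []
    for el in atoms.elements:
        el = str(el).upper()
        if el in _ELEMENT_TO_CATEGORY:
            cats.append(_ELEMENT_TO_CATEGORY[el])
        else:
            warnings.warn(f"element {el!r} has no LJ category; treating as CS")
            cats.append("CS")
    atoms.categories = np.asarray(cats, dtype=object)

    rmin_half: dict[str, float] = {}
    eps: dict[str, float] = {}
    for cat in LJ_CATEGORIES:
        members = [
            str(el).upper()
            for el, c in zip(atoms.elements, cats)
            if c == cat and str(el).upper() in table.index
        ]
        if members:
            rmin_half[cat] = float(np.mean([table.loc[m, "rmin_half_A"] for m in members]))
            eps[cat] = float(np.mean([table.loc[m, "epsilon_kJ_mol"] for m in members]))
        else:  # category unpopulated in this structure; keep table defaults
            defaults = {"H": "H", "ON": "O", "CS": "C"}
            rmin_half[cat] = float(table.loc[defaults[cat], "rmin_half_A"])
            eps[cat] = float(table.loc[defaults[cat], "epsilon_kJ_mol"])
    return atoms, LJCategoryParams(rmin_half, eps)


def _grid_nodes(receptor: AtomSet, spacing: float, margin_A: float) -> tuple[np.ndarray, tuple]:
    lo = receptor.coords.min(axis=0) - margin_A
    hi = receptor.coords.max(axis=0) + margin_A
    dims = tuple(int(np.ceil((hi[k] - lo[k]) / spacing)) + 1 for k in range(3))
    return lo, dims


def _node_coordinates(origin, dims, spacing):
    axes = [origin[k] + spacing * np.arange(dims[k]) for k in range(3)]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)


def electrostatic_grid(
    receptor: AtomSet,
    ionic_strength_mM: float = 250.0,
    temperature_K: float = 298.0,
    spacing: float = 1.0,
    margin_A: float = 30.0,
) -> PotentialGrid:
    """Debye-Hueckel screened Coulomb potential of a unit positive probe charge.

    U(node) = sum_i [ke / eps_r] q_i exp(-r_i / lambda_D) / r_i  (kJ/mol/e).
    Distances are floored at half a grid spacing to keep node values finite
    inside atoms (the LJ grids dominate there anyway).
    """
    origin, dims = _grid_nodes(receptor, spacing, margin_A)
    nodes = _node_coordinates(origin, dims, spacing)
    lam = debye_length_A(ionic_strength_mM, temperature_K)
    pref = COULOMB_KJ_A / WATER_DIELECTRIC
    values = np.zeros(len(nodes))
    charged = np.abs(receptor.charges) > 0
    coords = receptor.coords[charged]
    qs = receptor.charges[charged]
    chunk = max(1, int(2e6 // max(len(coords), 1)))
    for s in range(0, len(nodes), chunk):
        d = np.linalg.norm(nodes[s : s + chunk, None, :] - coords[None, :, :], axis=-1)
        d = np.maximum(d, 0.5 * spacing)
        scr = np.exp(-d / lam) if np.isfinite(lam) else 1.0
        values[s : s + chunk] = (pref * qs[None, :] * scr / d).sum(axis=1)
    return PotentialGrid(origin, spacing, values.reshape(dims), kind="electrostatic")


def lj_grid(
    receptor: AtomSet,
    category_params: LJCategoryParams,
    category: str,
    spacing: float = 1.0,
    cap_kJ_mol: float = DEFAULT_LJ_CAP_KJ_MOL,
    margin_A: float = 30.0,
) -> PotentialGrid:
    """12-6 Lennard-Jones energy of a probe atom of ``category`` at each node.

    U = sum_i eps_i [ (Rmin_i/r)^12 - 2 (Rmin_i/r)^6 ] with Lorentz-Berthelot
    combination against each receptor atom's element parameters; values are
    clipped at ``cap_kJ_mol`` so clash regions stay finite.
    """
    if category not in LJ_CATEGORIES:
        raise ValueError(f"unknown LJ category {category!r}")
    table = load_atom_params()
    origin, dims = _grid_nodes(receptor, spacing, margin_A)
    nodes = _node_coordinates(origin, dims, spacing)

    rh_atoms = np.array(
        [
            float(table.loc[str(el).upper(), "rmin_half_A"])
            if str(el).upper() in table.index
            else float(table.loc["C", "rmin_half_A"])
            for el in receptor.elements
        ]
    )
    eps_atoms = np.array(
        [
            float(table.loc[str(el).upper(), "epsilon_kJ_mol"])
            if str(el).upper() in table.index
            else float(table.loc["C", "epsilon_kJ_mol"])
            for el in receptor.elements
        ]
    )
    rmin = category_params.rmin_half_A[category] + rh_atoms
    eps = np.sqrt(category_params.epsilon_kJ_mol[category] * eps_atoms)

    values = np.zeros(len(nodes))
    chunk = max(1, int(2e6 // max(len(receptor), 1)))
    for s in range(0, len(nodes), chunk):
        d = np.linalg.norm(
            nodes[s : s + chunk, None, :] - receptor.coords[None, :, :], axis=-1
        )
        d = np.maximum(d, 1e-3)
        sr6 = (rmin[None, :] / d) ** 6
        values[s : s + chunk] = (eps[None, :] * (sr6**2 - 2 * sr6)).sum(axis=1)
    values = np.minimum(values, cap_kJ_mol)
    return PotentialGrid(origin, spacing, values.reshape(dims), kind=f"LJ_{category}")


def smooth_grid(grid: PotentialGrid, width_A: float = 1.0) -> PotentialGrid:
    """Separable 3D Gaussian smoothing with sigma = width (nearest-edge padding)."""
    sigma = width_A / grid.spacing
    return PotentialGrid(
        grid.origin.copy(),
        grid.spacing,
        gaussian_filter(grid.values, sigma=sigma, mode="nearest"),
        kind=grid.kind,
    )


def build_gridset(
    receptor: AtomSet,
    ionic_strength_mM: float = 250.0,
    temperature_K: float = 298.0,
    spacing: float = 1.0,
    margin_A: float = 30.0,
    smoothing_width_A: float = 1.0,
    cap_kJ_mol: float = DEFAULT_LJ_CAP_KJ_MOL,
    mobile_atoms: AtomSet | None = None,
) -> GridSet:
    """Build the full smoothed grid set for one receptor.

    Category parameters are averaged over the mobile protein's atoms when
    given (that is whose categories the grids represent), otherwise over the
    receptor's.
    """
    _, params = assign_lj_categories(mobile_atoms if mobile_atoms is not None else receptor)
    elec = electrostatic_grid(receptor, ionic_strength_mM, temperature_K, spacing, margin_A)
    grids = {
        cat: lj_grid(receptor, params, cat, spacing, cap_kJ_mol, margin_A)
        for cat in LJ_CATEGORIES
    }
    if smoothing_width_A > 0:
        elec = smooth_grid(elec, smoothing_width_A)
        grids = {c: smooth_grid(g, smoothing_width_A) for c, g in grids.items()}
    return GridSet(electrostatic=elec, lj=grids, category_params=params)


def interpolate(grid: PotentialGrid, points) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear value and analytic gradient at one or many points.

    Points must lie inside the grid bounds; the Brownian propagator applies
    its harmonic wall before calling this.
    """
    single = np.asarray(points, dtype=float).ndim == 1
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    rel = (pts - grid.origin) / grid.spacing
    dims = np.array(grid.dims)
    if np.any(rel < -1e-9) or np.any(rel > dims - 1 + 1e-9):
        raise ValueError("point outside grid bounds")
    i0 = np.clip(np.floor(rel).astype(int), 0, dims - 2)
    f = rel - i0

    v = grid.values
    ix, iy, iz = i0[:, 0], i0[:, 1], i0[:, 2]
    c = np.empty((len(pts), 2, 2, 2))
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                c[:, dx, dy, dz] = v[ix + dx, iy + dy, iz + dz]

    wx = np.stack([1 - f[:, 0], f[:, 0]], axis=1)
    wy = np.stack([1 - f[:, 1], f[:, 1]], axis=1)
    wz = np.stack([1 - f[:, 2], f[:, 2]], axis=1)
    dwx = np.stack([-np.ones(len(pts)), np.ones(len(pts))], axis=1)

    val = np.einsum("nxyz,nx,ny,nz->n", c, wx, wy, wz)
    gx = np.einsum("nxyz,nx,ny,nz->n", c, dwx, wy, wz) / grid.spacing
    gy = np.einsum("nxyz,nx,ny,nz->n", c, wx, dwx, wz) / grid.spacing
    gz = np.einsum("nxyz,nx,ny,nz->n", c, wx, wy, dwx) / grid.spacing
    grad = np.stack([gx, gy, gz], axis=1)
    if single:
        return float(val[0]), grad[0]
    return val, grad


def write_gridset(gridset: GridSet, out_dir) -> None:
    """Write each grid as an OpenDX scalar field plus the category parameters."""
    from gridData import Grid as DXGrid

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, g in [("electrostatic", gridset.electrostatic)] + [
        (f"lj_{c}", gridset.lj[c]) for c in gridset.lj
    ]:
        dx = DXGrid(g.values, origin=g.origin, delta=g.spacing)
        dx.export(str(out / f"{name}.dx"), file_format="dx")
    with open(out / "lj_categories.tsv", "w") as fh:
        fh.write("category\trmin_half_A\tepsilon_kJ_mol\n")
        for c in LJ_CATEGORIES:
            fh.write(
                f"{c}\t{gridset.category_params.rmin_half_A[c]:.6f}\t"
                f"{gridset.category_params.epsilon_kJ_mol[c]:.6f}\n"
            )


def read_gridset(in_dir) -> GridSet:
    """Read a grid set written by :func:`write_gridset`."""
    from gridData import Grid as DXGrid

    src = Path(in_dir)
    rmin_half: dict[str, float] = {}
    eps: dict[str, float] = {}
    with open(src / "lj_categories.tsv") as fh:
        next(fh)
        for line in fh:
            c, rh, e = line.split("\t")
            rmin_half[c] = float(rh)
            eps[c] = float(e)

    def load(name: str, kind: str) -> PotentialGrid:
        dx = DXGrid(str(src / f"{name}.dx"))
        return PotentialGrid(
            np.asarray(dx.origin), float(dx.delta[0]), np.asarray(dx.grid), kind=kind
        )

    return GridSet(
        electrostatic=load("electrostatic", "electrostatic"),
        lj={c: load(f"lj_{c}", f"LJ_{c}") for c in LJ_CATEGORIES},
        category_params=LJCategoryParams(rmin_half, eps),
    )
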