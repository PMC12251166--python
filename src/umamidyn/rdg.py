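"""Reduced density gradient (NCI) analysis on promolecular densities.

The electron density is approximated as a superposition of spherically
averaged free-atom densities (the standard promolecular approximation for
NCI work).  Each atomic density is built from Slater-type orbitals with
Slater's-rules screening exponents, so it is analytic, strictly positive,
and integrates exactly to the element's electron count; elements H through
Kr are supported.

The reduced density gradient is

    RDG = |grad rho| / ( 2 (3 pi^2)^(1/3) rho^(4/3) )

evaluated by central differences on a uniform grid; weak-interaction voxels
(low RDG, low density) are classified by sign(lambda2) * rho, where lambda2
is the middle eigenvalue of the density Hessian: negative = hydrogen bond,
near zero = van der Waals, positive = steric repulsion.

Internally densities and derivatives are in atomic units (Bohr); grid
geometry is stated in Angstrom at the interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import gamma as _gamma

from .structure import StructureModel

__all__ = [
    "ScalarFieldGrid", "atomic_density", "promolecular_density", "rdg",
    "classify_nci", "export_cube", "read_cube", "ELEMENT_Z",
]

BOHR_PER_ANGSTROM = 1.8897259886
RDG_PREFACTOR = 1.0 / (2.0 * (3.0 * np.pi ** 2) ** (1.0 / 3.0))
RHO_FLOOR = 1e-8  # a.u.; voxels below are masked from RDG

ELEMENT_Z = {
    "H": 1, "HE": 2, "LI": 3, "BE": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "NE": 10, "NA": 11, "MG": 12, "AL": 13, "SI": 14, "P": 15,
    "S": 16, "CL": 17, "AR": 18, "K": 19, "CA": 20, "SC": 21, "TI": 22,
    "V": 23, "CR": 24, "MN": 25, "FE": 26, "CO": 27, "NI": 28, "CU": 29,
    "ZN": 30, "GA": 31, "GE": 32, "AS": 33, "SE": 34, "BR": 35, "KR": 36,
}
_Z_ELEMENT = {z: el for el, z in ELEMENT_Z.items()}

NCI_LABELS = {0: "none", 1: "hydrogen-bond", 2: "van-der-waals", 3: "steric"}


# ---------------------------------------------------------------------------
# Slater's-rules atomic densities


def _configuration(z: int) -> dict:
    """Electrons per subshell for ground-state atoms up to Kr (Aufbau with
    the Cr and Cu exceptions)."""
    order = [("1s", 2), ("2s", 2), ("2p", 6), ("3s", 2), ("3p", 6),
             ("4s", 2), ("3d", 10), ("4p", 6)]
    conf: dict = {}
    remaining = z
    for shell, cap in order:
        take = min(cap, remaining)
        if take:
            conf[shell] = take
        remaining -= take
        if remaining == 0:
            break
    if z == 24:  # Cr: 3d5 4s1
        conf["4s"], conf["3d"] = 1, 5
    if z == 29:  # Cu: 3d10 4s1
        conf["4s"], conf["3d"] = 1, 10
    return conf


_GROUPS = [("1s",), ("2s", "2p"), ("3s", "3p"), ("3d",), ("4s", "4p")]
_N_STAR = {1: 1.0, 2: 2.0, 3: 3.0, 4: 3.7}


def _slater_shells(z: int):
    """(occupancy, n_star, zeta) per Slater group for element Z."""
    conf = _configuration(z)
    group_occ = [sum(conf.get(s, 0) for s in grp) for grp in _GROUPS]
    shells = []
    for gi, grp in enumerate(_GROUPS):
        occ = group_occ[gi]
        if occ == 0:
            continue
        n = int(grp[0][0])
        is_d = grp == ("3d",)
        same = 0.30 if grp == ("1s",) else 0.35
        sigma = same * (occ - 1)
        if is_d:
            sigma += sum(group_occ[:gi])
        else:
            for gj in range(gi):
                n_j = int(_GROUPS[gj][0][0])
                sigma += (0.85 if n_j == n - 1 else 1.00) * group_occ[gj]
        zeta = (z - sigma) / _N_STAR[n]
        shells.append((occ, _N_STAR[n], max(zeta, 0.1)))
    return shells


def atomic_density(element: str, r):
    """Spherically averaged free-atom density (a.u.) at radius r (Bohr).

    Integrates exactly to the element's electron count.
    """
    el = element.upper()
    if el not in ELEMENT_Z:
        raise ValueError(f"unsupported element {element!r} (H through Kr)")
    r = np.maximum(np.asarray(r, dtype=float), 1e-12)
    rho = np.zeros_like(r)
    for occ, n_star, zeta in _slater_shells(ELEMENT_Z[el]):
        norm2 = (2 * zeta) ** (2 * n_star + 1) / _gamma(2 * n_star + 1)
        rho += occ * norm2 * r ** (2 * n_star - 2) * np.exp(-2 * zeta * r) / (4 * np.pi)
    return rho


# ---------------------------------------------------------------------------
# grids


@dataclass
class ScalarFieldGrid:
    """Uniform 3-D grid holding the density and its derived fields.

    origin/spacing are in Angstrom; rho, grad_norm (a.u. per Bohr), lambda2
    and rdg are voxel arrays of shape dims, filled progressively.
    """

    origin: np.ndarray
    spacing: np.ndarray  # per-axis, Angstrom
    dims: tuple
    rho: np.ndarray | None = None
    grad_norm: np.ndarray | None = None
    lambda2: np.ndarray | None = None
    rdg: np.ndarray | None = None
    structure: StructureModel | None = None

    def axes(self):
        """Per-axis voxel-center coordinates (Angstrom)."""
        return [self.origin[i] + self.spacing[i] * np.arange(self.dims[i])
                for i in range(3)]

    def voxel_coordinates(self):
        ax = self.axes()
        x, y, z = np.meshgrid(*ax, indexing="ij")
        return x, y, z


def promolecular_density(structure: StructureModel, spacing: float = 0.2,
                         margin: float = 3.0, origin=None, dims=None
                         ) -> ScalarFieldGrid:
    """Promolecular density of a structure on a uniform grid.

    The grid spans the structure's bounding box plus ``margin`` Angstrom
    unless origin/dims are given explicitly.
    """
    for el in structure.elements:
        if el not in ELEMENT_Z:
            raise ValueError(f"unsupported element {el!r} (H through Kr)")
    spacing3 = np.full(3, float(spacing))
    if origin is None:
        lo = structure.coords.min(axis=0) - margin
        hi = structure.coords.max(axis=0) + margin
        origin = lo
        dims = tuple(int(np.ceil((hi[i] - lo[i]) / spacing)) + 1 for i in range(3))
    grid = ScalarFieldGrid(origin=np.asarray(origin, float), spacing=spacing3,
                           dims=tuple(dims), structure=structure)
    x, y, z = grid.voxel_coordinates()
    rho = np.zeros(grid.dims)
    for i in range(structure.n_atoms):
        cx, cy, cz = structure.coords[i]
        r_bohr = BOHR_PER_ANGSTROM * np.sqrt(
            (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2)
        rho += atomic_density(structure.elements[i], r_bohr)
    grid.rho = rho
    return grid


def rdg(grid: ScalarFieldGrid, rho_floor: float = RHO_FLOOR) -> ScalarFieldGrid:
    """Fill grad_norm, lambda2 and rdg from the grid's density.

    Central differences (one-sided at boundaries); voxels with density below
    ``rho_floor`` are masked (NaN).  Requires near-uniform spacing.
    """
    if grid.rho is None:
        raise ValueError("grid density is not filled")
    sp = grid.spacing
    if sp.max() / sp.min() > 1.01:
        raise ValueError("grid spacing non-uniform beyond 1%")
    h = sp * BOHR_PER_ANGSTROM  # derivatives taken in atomic units
    gx, gy, gz = np.gradient(grid.rho, h[0], h[1], h[2])
    grid.grad_norm = np.sqrt(gx ** 2 + gy ** 2 + gz ** 2)

    rows = []
    for gi in (gx, gy, gz):
        rows.append(np.gradient(gi, h[0], h[1], h[2]))
    hess = np.stack([np.stack(r, axis=-1) for r in rows], axis=-2)
    hess = 0.5 * (hess + np.swapaxes(hess, -1, -2))
    evals = np.linalg.eigvalsh(hess.reshape(-1, 3, 3)).reshape(*grid.dims, 3)
    grid.lambda2 = evals[..., 1]  # middle eigenvalue, ascending order

    mask = grid.rho >= rho_floor
    s = np.full(grid.dims, np.nan)
    s[mask] = (RDG_PREFACTOR * grid.grad_norm[mask]
               / grid.rho[mask] ** (4.0 / 3.0))
    grid.rdg = s
    return grid


def classify_nci(grid: ScalarFieldGrid, rdg_isovalue: float = 0.5,
                 rho_cutoff: float = 0.05, signed_rho_threshold: float = 0.01):
    """Label weak-interaction voxels by sign(lambda2) * rho.

    Among interior voxels with RDG below the isovalue and density below the
    cutoff: hydrogen-bond where sign(lambda2)*rho < -threshold, steric where
    > +threshold, van der Waals in between.  Returns (label array, counts).
    """
    for name in ("rho", "rdg", "lambda2"):
        if getattr(grid, name) is None:
            raise ValueError(f"grid field {name!r} is not filled")
    labels = np.zeros(grid.dims, dtype=np.int8)
    interior = np.zeros(grid.dims, bool)
    interior[1:-1, 1:-1, 1:-1] = True  # boundary stencils are one-sided
    candidate = (interior & np.isfinite(grid.rdg)
                 & (grid.rdg < rdg_isovalue) & (grid.rho < rho_cutoff))
    signed = np.sign(grid.lambda2) * grid.rho
    labels[candidate & (signed < -signed_rho_threshold)] = 1
    labels[candidate & (np.abs(signed) <= signed_rho_threshold)] = 2
    labels[candidate & (signed > signed_rho_threshold)] = 3
    counts = {NCI_LABELS[k]: int((labels == k).sum()) for k in (1, 2, 3)}
    return labels, counts


# ---------------------------------------------------------------------------
# Gaussian cube input/output


def export_cube(grid: ScalarFieldGrid, field_name: str, path,
                comment: str = "umamidyn scalar field") -> None:
    """Write one grid field in Gaussian cube format (Bohr units, z-fastest
    voxel order).  NaN-masked voxels are written as 0."""
    values = getattr(grid, field_name, None)
    if values is None:
        raise ValueError(f"grid field {field_name!r} is not filled")
    atoms = grid.structure
    n_atoms = 0 if atoms is None else atoms.n_atoms
    lines = [comment, f"field: {field_name}"]
    o = grid.origin * BOHR_PER_ANGSTROM
    lines.append(f"{n_atoms:5d}{o[0]:12.6f}{o[1]:12.6f}{o[2]:12.6f}")
    for i in range(3):
        v = np.zeros(3)
        v[i] = grid.spacing[i] * BOHR_PER_ANGSTROM
        lines.append(f"{grid.dims[i]:5d}{v[0]:12.6f}{v[1]:12.6f}{v[2]:12.6f}")
    if atoms is not None:
        for i in range(n_atoms):
            z = ELEMENT_Z[atoms.elements[i]]
            c = atoms.coords[i] * BOHR_PER_ANGSTROM
            lines.append(f"{z:5d}{float(z):12.6f}{c[0]:12.6f}{c[1]:12.6f}{c[2]:12.6f}")
    flat = np.nan_to_num(values).reshape(-1)  # x slowest, z fastest
    for start in range(0, len(flat), 6):
        chunk = flat[start:start + 6]
        lines.append("".join(f"{v:14.6e}" for v in chunk))
    Path(path).write_text("\n".join(lines) + "\n")


def read_cube(path):
    """Read a Gaussian cube file written by ``export_cube``.

    Returns (ScalarFieldGrid with the field in ``rho``, atom list of
    (element, coordinates Angstrom)).
    """
    lines = Path(path).read_text().splitlines()
    n_atoms = int(lines[2].split()[0])
    origin = np.array([float(v) for v in lines[2].split()[1:4]]) / BOHR_PER_ANGSTROM
    dims = []
    spacing = []
    for i in range(3):
        parts = lines[3 + i].split()
        dims.append(int(parts[0]))
        vec = np.array([float(v) for v in parts[1:4]])
        spacing.append(np.linalg.norm(vec) / BOHR_PER_ANGSTROM)
    atoms = []
    for i in range(n_atoms):
        parts = lines[6 + i].split()
        z = int(parts[0])
        coords = np.array([float(v) for v in parts[2:5]]) / BOHR_PER_ANGSTROM
        atoms.append((_Z_ELEMENT[z], coords))
    values = np.fromstring(" ".join(lines[6 + n_atoms:]), sep=" ")
    grid = ScalarFieldGrid(origin=origin, spacing=np.asarray(spacing),
                           dims=tuple(dims), rho=values.reshape(tuple(dims)))
    return grid, atoms
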