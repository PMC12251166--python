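"""Structures, trajectories, PDB input/output, superposition and pocket
geometry.

The in-memory containers are array-backed: ``StructureModel`` holds one
conformation of N atoms, ``Trajectory`` stacks F conformations over a shared
topology.  Multi-MODEL PDB files map to trajectories.  Parsing and writing of
the fixed-width format is delegated to biotite; a pre-scan supplies precise
error locations (line numbers, per-model atom counts) before biotite sees the
file.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile
from scipy.spatial.transform import Rotation

from .params import vdw_radius

__all__ = [
    "AtomRecord", "StructureModel", "Trajectory",
    "read_pdb", "write_pdb", "kabsch_superpose", "bounding_box",
]


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, position, and the physical parameters the
    analysis layers need (vdW radius always, partial charge optionally)."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain: str
    coordinates: tuple
    vdw_radius: float
    partial_charge: float | None = None


class StructureModel:
    """Array-backed single-conformation structure.

    Parameters are parallel arrays/lists over atoms.  ``charges`` is optional
    (None until assigned).  Equality of (chain, residue_number, name) triples
    is enforced as uniqueness.
    """

    def __init__(self, serials, names, elements, res_names, res_numbers,
                 chains, coords, vdw=None, charges=None):
        self.serials = np.asarray(serials, dtype=int)
        self.names = list(names)
        self.elements = [e.upper() for e in elements]
        self.res_names = list(res_names)
        self.res_numbers = np.asarray(res_numbers, dtype=int)
        self.chains = list(chains)
        self.coords = np.asarray(coords, dtype=float)
        if self.coords.shape != (len(self.names), 3):
            raise ValueError("coordinate array must be (n_atoms, 3)")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")
        if vdw is None:
            vdw = [vdw_radius(e) for e in self.elements]
        self.vdw = np.asarray(vdw, dtype=float)
        if (self.vdw <= 0).any():
            raise ValueError("vdW radii must be positive")
        self.charges = None if charges is None else np.asarray(charges, dtype=float)
        keys = list(zip(self.chains, self.res_numbers.tolist(), self.names))
        if len(set(keys)) != len(keys):
            raise ValueError("(chain, residue_number, name) must be unique")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def atom(self, i: int) -> AtomRecord:
        q = None if self.charges is None else float(self.charges[i])
        return AtomRecord(
            int(self.serials[i]), self.names[i], self.elements[i],
            self.res_names[i], int(self.res_numbers[i]), self.chains[i],
            tuple(self.coords[i]), float(self.vdw[i]), q)

    def __len__(self) -> int:
        return self.n_atoms

    def __iter__(self):
        return (self.atom(i) for i in range(self.n_atoms))

    def atom_keys(self) -> list[tuple]:
        """(chain, residue_number, residue_name, atom name) per atom."""
        return [
            (self.chains[i], int(self.res_numbers[i]), self.res_names[i], self.names[i])
            for i in range(self.n_atoms)
        ]

    def residue_index(self) -> dict:
        """(chain, residue_number) -> array of atom indices, in atom order."""
        index: dict = {}
        for i in range(self.n_atoms):
            index.setdefault((self.chains[i], int(self.res_numbers[i])), []).append(i)
        return {k: np.asarray(v, dtype=int) for k, v in index.items()}

    def select(self, *, name=None, element=None, res_name=None, chain=None,
               heavy=False) -> np.ndarray:
        """Atom indices matching all given criteria (each a value or set)."""
        def match(values, crit):
            if crit is None:
                return np.ones(self.n_atoms, bool)
            crit = {crit} if isinstance(crit, str) else set(crit)
            return np.asarray([v in crit for v in values])

        mask = (match(self.names, name) & match(self.elements, element)
                & match(self.res_names, res_name) & match(self.chains, chain))
        if heavy:
            mask &= np.asarray([e != "H" for e in self.elements])
        return np.nonzero(mask)[0]

    def subset(self, indices) -> "StructureModel":
        idx = np.asarray(indices, dtype=int)
        return StructureModel(
            self.serials[idx], [self.names[i] for i in idx],
            [self.elements[i] for i in idx], [self.res_names[i] for i in idx],
            self.res_numbers[idx], [self.chains[i] for i in idx],
            self.coords[idx], self.vdw[idx],
            None if self.charges is None else self.charges[idx])

    def with_coords(self, coords) -> "StructureModel":
        return StructureModel(
            self.serials, self.names, self.elements, self.res_names,
            self.res_numbers, self.chains, coords, self.vdw, self.charges)


@dataclass
class Trajectory:
    """Ordered conformations over a shared topology.

    coords: (n_frames, n_atoms, 3) Angstrom; times in ps (strictly increasing
    when present); potential energies in kcal/mol when present.
    """

    topology: StructureModel
    coords: np.ndarray
    times: np.ndarray | None = None
    energies: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError("frames must be (n_frames, n_atoms, 3) matching topology")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if len(self.times) != self.n_frames:
                raise ValueError("times length must match frame count")
            if (np.diff(self.times) <= 0).any():
                raise ValueError("times must be strictly increasing")
        if self.energies is not None:
            self.energies = np.asarray(self.energies, dtype=float)
            if len(self.energies) != self.n_frames:
                raise ValueError("energies length must match frame count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> StructureModel:
        return self.topology.with_coords(self.coords[i])


# ---------------------------------------------------------------------------
# PDB input/output


def _prescan_pdb(text: str, path) -> None:
    """Validate fixed-width ATOM/HETATM records and per-MODEL atom counts,
    raising with the offending line or model named."""
    counts: list[int] = []
    current = 0
    in_model = False
    seen_model = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec in ("ATOM", "HETATM"):
            if len(line) < 54:
                raise ValueError(f"{path}: malformed ATOM record at line {lineno} "
                                 "(shorter than coordinate columns)")
            try:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except ValueError:
                raise ValueError(
                    f"{path}: unparseable coordinates at line {lineno}") from None
            current += 1
        elif rec == "MODEL":
            if in_model:
                counts.append(current)
            in_model, seen_model, current = True, True, 0
        elif rec == "ENDMDL":
            counts.append(current)
            in_model, current = False, 0
    if current and (in_model or not seen_model):
        counts.append(current)
    if len(set(counts)) > 1:
        bad = next(i for i, c in enumerate(counts, start=1) if c != counts[0])
        raise ValueError(
            f"{path}: inconsistent atom count in MODEL {bad} "
            f"({counts[bad - 1]} atoms vs {counts[0]} in MODEL 1)")


_GUESSABLE = ("H", "C", "N", "O", "S", "P")


def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {name!r}")


def _from_atom_array(arr: bst.AtomArray) -> StructureModel:
    elements = []
    for el, nm in zip(arr.element, arr.atom_name):
        el = el.strip().upper()
        elements.append(el if el else _element_from_name(nm))
    n = arr.array_length()
    return StructureModel(
        serials=np.arange(1, n + 1),
        names=[str(a) for a in arr.atom_name],
        elements=elements,
        res_names=[str(r) for r in arr.res_name],
        res_numbers=arr.res_id,
        chains=[str(c) if str(c).strip() else "A" for c in arr.chain_id],
        coords=arr.coord,
    )


def read_pdb(path):
    """Read a PDB file: one MODEL -> StructureModel, several -> Trajectory.

    Elements come from columns 77-78 with an atom-name fallback; vdW radii
    are assigned from the element table.
    """
    path = Path(path)
    text = path.read_text()
    _prescan_pdb(text, path)
    pdb = PDBFile.read(io.StringIO(text))
    stack = pdb.get_structure()
    if stack.stack_depth() == 1:
        return _from_atom_array(stack[0])
    topo = _from_atom_array(stack[0])
    return Trajectory(topology=topo, coords=stack.coord.copy())


def _to_atom_array(model: StructureModel, coords=None) -> bst.AtomArray:
    n = model.n_atoms
    arr = bst.AtomArray(n)
    arr.coord = np.asarray(model.coords if coords is None else coords, dtype=np.float32)
    arr.atom_name = np.asarray(model.names)
    arr.element = np.asarray(model.elements)
    arr.res_name = np.asarray(model.res_names)
    arr.res_id = model.res_numbers
    arr.chain_id = np.asarray([c[:1] if c else "A" for c in model.chains])
    arr.hetero = np.zeros(n, bool)
    return arr


def write_pdb(obj, path) -> None:
    """Write a StructureModel or Trajectory (MODEL/ENDMDL) as PDB."""
    pdb = PDBFile()
    if isinstance(obj, Trajectory):
        n = obj.topology.n_atoms
        stack = bst.AtomArrayStack(obj.n_frames, n)
        template = _to_atom_array(obj.topology)
        for cat in ("atom_name", "element", "res_name", "res_id", "chain_id", "hetero"):
            stack.set_annotation(cat, template.get_annotation(cat))
        stack.coord = obj.coords.astype(np.float32)
        pdb.set_structure(stack)
    else:
        pdb.set_structure(_to_atom_array(obj))
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Superposition and pocket geometry


def kabsch_superpose(mobile, reference, selection=None):
    """Least-squares rigid superposition of mobile onto reference.

    Returns (rotation 3x3 with det +1, translation 3-vector, rmsd Angstrom)
    such that ``mobile @ R.T + t`` best fits the reference over the
    selection.  The RMSD is sqrt(mean of squared residual distances).
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if selection is not None:
        sel = np.asarray(selection, dtype=int)
        mob, ref = mob[sel], ref[sel]
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("mobile and reference selections must be matching (n, 3)")
    n = mob.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 atoms")
    mob_c = mob.mean(axis=0)
    ref_c = ref.mean(axis=0)
    mob0, ref0 = mob - mob_c, ref - ref_c
    # collinear selections leave a free rotation axis
    if np.linalg.matrix_rank(ref0, tol=1e-8) < 2 or np.linalg.matrix_rank(mob0, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) atom selection")
    rot, rssd = Rotation.align_vectors(ref0, mob0)
    matrix = rot.as_matrix()
    translation = ref_c - matrix @ mob_c
    return matrix, translation, float(rssd / np.sqrt(n))


def bounding_box(coords, radii=None):
    """Principal-axis bounding box of an atom set.

    Extents (sorted descending) along the eigenvectors of the coordinate
    covariance, padded by per-atom vdW radii; volume is their product.
    Requires at least 4 non-coplanar atoms.
    """
    xyz = np.asarray(coords, dtype=float)
    if xyz.ndim != 2 or xyz.shape[1] != 3 or xyz.shape[0] < 4:
        raise ValueError("bounding box needs at least 4 atoms of shape (n, 3)")
    r = np.zeros(len(xyz)) if radii is None else np.asarray(radii, dtype=float)
    centered = xyz - xyz.mean(axis=0)
    cov = centered.T @ centered / len(xyz)
    evals, axes = np.linalg.eigh(cov)
    if evals[0] < 1e-12 and (r <= 0).all():
        raise ValueError("atoms are coplanar; no 3-D box")
    proj = centered @ axes[:, ::-1]  # principal axes, descending variance
    extents = (proj + r[:, None]).max(axis=0) - (proj - r[:, None]).min(axis=0)
    extents = np.sort(extents)[::-1]
    return float(extents[0]), float(extents[1]), float(extents[2]), float(np.prod(extents))
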