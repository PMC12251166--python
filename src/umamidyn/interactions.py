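"""Hydrogen bonds and occupancy, contact fingerprints, solvent-accessible
surface area, pocket hydrophobicity and pocket water counting.

Hydrogen-bond geometric criteria: donor-acceptor distance below 3.5 Angstrom
and acceptor-hydrogen-donor angle (vertex at the hydrogen) above 135 degrees.
Occupancy is the fraction of trajectory frames in which a donor-acceptor pair
satisfies both; pairs above 45% occupancy are conventionally reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .params import KYTE_DOOLITTLE, THREE_TO_ONE
from .structure import StructureModel, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "HBond", "OccupancyTable", "detect_hbonds", "hbond_occupancy",
    "contact_residues", "sasa", "pocket_hydrophobicity", "count_pocket_waters",
]

HB_DISTANCE_MAX = 3.5   # Angstrom, donor-acceptor
HB_ANGLE_MIN = 135.0    # degrees, at the hydrogen vertex
OCCUPANCY_DEFAULT = 0.45

POLAR_ELEMENTS = frozenset({"N", "O", "S"})
APOLAR_ELEMENTS = frozenset({"C", "S"})
H_COVALENT_MAX = 1.25   # Angstrom, H considered bonded to a polar heavy atom
WATER_RESIDUES = frozenset({"HOH", "WAT", "SOL", "TIP3"})


@dataclass(frozen=True)
class HBond:
    donor: tuple
    hydrogen: tuple
    acceptor: tuple
    distance: float  # donor-acceptor, Angstrom
    angle: float     # acceptor-hydrogen-donor, degrees


@dataclass
class OccupancyTable:
    """(donor key, acceptor key) -> fraction of frames bonded."""

    fractions: dict
    n_frames: int
    min_occupancy: float = OCCUPANCY_DEFAULT

    def filtered(self, min_occupancy: float | None = None) -> dict:
        cut = self.min_occupancy if min_occupancy is None else min_occupancy
        return {k: v for k, v in self.fractions.items() if v >= cut - 1e-12}


def _polar_hydrogens(model: StructureModel, coords=None):
    """Map polar-heavy-atom index -> indices of covalently attached H."""
    xyz = model.coords if coords is None else coords
    heavy = [i for i, e in enumerate(model.elements) if e in POLAR_ELEMENTS]
    hydrogens = [i for i, e in enumerate(model.elements) if e == "H"]
    attached: dict = {i: [] for i in heavy}
    if heavy and hydrogens:
        d = cdist(xyz[heavy], xyz[hydrogens])
        for a, row in zip(heavy, d):
            attached[a] = [hydrogens[j] for j in np.nonzero(row < H_COVALENT_MAX)[0]]
    return attached


def _geometry_ok(d_xyz, h_xyz, a_xyz):
    dist = float(np.linalg.norm(a_xyz - d_xyz))
    if dist >= HB_DISTANCE_MAX:
        return None
    v1 = d_xyz - h_xyz
    v2 = a_xyz - h_xyz
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        return None
    cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
    angle = float(np.degrees(np.arccos(cosang)))
    if angle <= HB_ANGLE_MIN:
        return None
    return dist, angle


def detect_hbonds(model: StructureModel, coords=None, donors=None,
                  acceptors=None) -> list[HBond]:
    """All donor-H...acceptor triads satisfying both geometric criteria.

    Donors default to polar heavy atoms (N/O/S) with an attached hydrogen,
    acceptors to all polar heavy atoms.  Each qualifying donor-acceptor pair
    is reported once (best-angle hydrogen).  An explicitly supplied donor
    without an attached hydrogen is skipped with a logged warning.
    """
    xyz = model.coords if coords is None else np.asarray(coords, float)
    attached = _polar_hydrogens(model, xyz)
    if donors is None:
        donor_ids = [i for i, hs in attached.items() if hs]
    else:
        donor_ids = []
        for i in donors:
            if not attached.get(i):
                logger.warning("donor %s has no attached hydrogen; skipped",
                               model.atom_keys()[i])
                continue
            donor_ids.append(i)
    acceptor_ids = list(attached) if acceptors is None else list(acceptors)

    keys = model.atom_keys()
    bonds = []
    for d in donor_ids:
        for a in acceptor_ids:
            if a == d:
                continue
            best = None
            for h in attached[d]:
                geo = _geometry_ok(xyz[d], xyz[h], xyz[a])
                if geo and (best is None or geo[1] > best[1]):
                    best = (h, geo[1], geo[0])
            if best is not None:
                h, angle, dist = best
                bonds.append(HBond(keys[d], keys[h], keys[a], dist, angle))
    return bonds


def hbond_occupancy(traj: Trajectory, donors=None, acceptors=None,
                    min_occupancy: float = OCCUPANCY_DEFAULT) -> OccupancyTable:
    """Per-pair fraction of frames in which the H-bond criteria hold.

    The returned table lists every pair observed in at least one frame;
    ``filtered()`` applies the occupancy threshold (45% by default).
    """
    if traj.n_frames < 1:
        raise ValueError("trajectory has no frames")
    counts: dict = {}
    for k in range(traj.n_frames):
        for hb in detect_hbonds(traj.topology, coords=traj.coords[k],
                                donors=donors, acceptors=acceptors):
            counts[(hb.donor, hb.acceptor)] = counts.get((hb.donor, hb.acceptor), 0) + 1
    fractions = {pair: c / traj.n_frames for pair, c in counts.items()}
    return OccupancyTable(fractions=fractions, n_frames=traj.n_frames,
                          min_occupancy=min_occupancy)


def _merge(receptor: StructureModel, ligand: StructureModel) -> tuple:
    """Concatenate receptor and ligand into one model for cross H-bond
    detection; ligand chains are remapped to avoid key collisions."""
    n_r = receptor.n_atoms
    lig_chains = [f"z{c}" for c in ligand.chains]
    merged = StructureModel(
        np.arange(1, n_r + ligand.n_atoms + 1),
        receptor.names + ligand.names,
        receptor.elements + ligand.elements,
        receptor.res_names + ligand.res_names,
        np.concatenate([receptor.res_numbers, ligand.res_numbers]),
        receptor.chains + lig_chains,
        np.vstack([receptor.coords, ligand.coords]))
    return merged, n_r


def contact_residues(receptor: StructureModel, ligand: StructureModel,
                     cutoff: float = 4.0) -> list[dict]:
    """Receptor residues with any heavy atom within ``cutoff`` of any ligand
    heavy atom, each labeled by interaction class.

    Classes: ``hydrogen-bonding`` when a receptor-ligand H-bond fires within
    the residue, ``hydrophobic`` when its only contacts are apolar-apolar
    (C/S) pairs, ``polar`` otherwise.
    """
    if receptor.n_atoms == 0 or ligand.n_atoms == 0:
        raise ValueError("receptor and ligand selections must be nonempty")
    rec_heavy = receptor.select(heavy=True)
    lig_heavy = ligand.select(heavy=True)
    d = cdist(receptor.coords[rec_heavy], ligand.coords[lig_heavy])
    in_contact = d <= cutoff

    merged, n_r = _merge(receptor, ligand)
    hb_residues = set()
    for hb in detect_hbonds(merged):
        # keep only receptor<->ligand bonds (ligand chains are 'z'-prefixed)
        d_lig = hb.donor[0].startswith("z")
        a_lig = hb.acceptor[0].startswith("z")
        if d_lig != a_lig:
            rec_key = hb.acceptor if d_lig else hb.donor
            hb_residues.add((rec_key[0], rec_key[1]))

    results = []
    seen = set()
    for ri, row in zip(rec_heavy, in_contact):
        if not row.any():
            continue
        res_key = (receptor.chains[ri], int(receptor.res_numbers[ri]))
        if res_key in seen:
            continue
        # gather every contacting atom of this residue
        res_atoms = [i for i in rec_heavy
                     if (receptor.chains[i], int(receptor.res_numbers[i])) == res_key]
        pairs = []
        for i in res_atoms:
            ci = np.nonzero(rec_heavy == i)[0][0]
            for cj in np.nonzero(in_contact[ci])[0]:
                pairs.append((i, lig_heavy[cj]))
        if not pairs:
            continue
        seen.add(res_key)
        if res_key in hb_residues:
            label = "hydrogen-bonding"
        elif all(receptor.elements[i] in APOLAR_ELEMENTS
                 and ligand.elements[j] in APOLAR_ELEMENTS for i, j in pairs):
            label = "hydrophobic"
        else:
            label = "polar"
        results.append({
            "chain": res_key[0],
            "residue_number": res_key[1],
            "residue_name": receptor.res_names[res_atoms[0]],
            "min_distance": float(min(np.linalg.norm(
                receptor.coords[i] - ligand.coords[j]) for i, j in pairs)),
            "interaction": label,
        })
    return results


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def sasa(model: StructureModel, probe: float = 1.4, n_points: int = 960,
         radii=None):
    """Shrake-Rupley solvent-accessible surface area.

    Returns (per-atom areas, total) in Angstrom^2.  Radii default to the
    model's vdW assignments; an explicit array may override them.
    """
    r = model.vdw if radii is None else np.asarray(radii, float)
    if len(r) != model.n_atoms:
        raise ValueError("radius array must match atom count")
    bad = np.nonzero(~(r > 0))[0]
    if len(bad):
        raise ValueError(f"missing/invalid radius for atom {model.atom_keys()[bad[0]]}")
    sphere = _fibonacci_sphere(n_points)
    expanded = r + probe
    tree = cKDTree(model.coords)
    areas = np.zeros(model.n_atoms)
    r_max = expanded.max()
    for i in range(model.n_atoms):
        pts = model.coords[i] + expanded[i] * sphere
        neighbors = [j for j in tree.query_ball_point(model.coords[i],
                                                      expanded[i] + r_max)
                     if j != i]
        accessible = np.ones(n_points, bool)
        for j in neighbors:
            d2 = ((pts - model.coords[j]) ** 2).sum(axis=1)
            accessible &= d2 > expanded[j] ** 2
        areas[i] = accessible.mean() * 4.0 * np.pi * expanded[i] ** 2
    return areas, float(areas.sum())


def pocket_hydrophobicity(model: StructureModel, pocket_selection,
                          scale=None, probe: float = 1.4) -> float:
    """SASA-weighted mean hydropathy of the pocket residues.

    Positive values indicate a hydrophobic pocket, negative a hydrophilic
    one; only the sign and the ordering between pockets are meaningful.
    """
    sel = np.asarray(pocket_selection, dtype=int)
    if len(sel) == 0:
        raise ValueError("pocket selection is empty")
    scale = KYTE_DOOLITTLE if scale is None else scale
    areas, _ = sasa(model, probe=probe)
    weighted = 0.0
    total = 0.0
    for i in sel:
        res3 = model.res_names[i]
        if res3 not in THREE_TO_ONE:
            raise ValueError(f"non-standard pocket residue {res3!r}")
        h = scale[THREE_TO_ONE[res3]]
        weighted += h * areas[i]
        total += areas[i]
    if total == 0:
        return 0.0
    return float(weighted / total)


def count_pocket_waters(traj: Trajectory, pocket_selection,
                        cutoff: float = 5.0, tail_fraction: float = 0.25):
    """Per-frame count of water oxygens within ``cutoff`` of any pocket heavy
    atom, plus the mean over the final ``tail_fraction`` of frames.

    Returns (counts array, tail mean).  Waters are recognized by residue name
    (HOH/WAT/SOL); a topology without waters yields zeros with a warning.
    """
    topo = traj.topology
    pocket = np.asarray(pocket_selection, dtype=int)
    pocket = pocket[[topo.elements[i] != "H" for i in pocket]]
    water_o = [i for i in range(topo.n_atoms)
               if topo.res_names[i] in WATER_RESIDUES and topo.elements[i] == "O"]
    counts = np.zeros(traj.n_frames, dtype=int)
    if not water_o:
        logger.warning("topology contains no water residues")
    else:
        for k in range(traj.n_frames):
            tree = cKDTree(traj.coords[k][pocket])
            near = tree.query_ball_point(traj.coords[k][water_o], cutoff)
            counts[k] = sum(1 for hits in near if hits)
    n_tail = max(1, int(np.ceil(tail_fraction * traj.n_frames)))
    return counts, float(counts[-n_tail:].mean())
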