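"""Synthetic input generation with planted ground truth.

Every downstream stage (screening, trajectory metrics, H-bond occupancy,
channel profiling, SIE, RDG) can be exercised on objects produced here; each
generator returns the object together with the planted parameters so tests
can assert recovery.  Identical seeds give identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.spatial.transform import Rotation

from .params import STANDARD_AA, vdw_radius
from .peptide_db import enumerate_dipeptides
from .structure import StructureModel, Trajectory

__all__ = [
    "SyntheticSpec", "generate",
    "make_dipeptide_structure", "make_trajectory", "make_channel_structure",
    "make_hbond_trajectory", "make_score_table", "write_truth_sidecar",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Declarative description of one synthetic artifact."""

    kind: str  # dipeptide | toy_receptor | trajectory | channel | water_shell | score_table
    parameters: dict = field(default_factory=dict)
    seed: int = 0

    _KINDS = ("dipeptide", "toy_receptor", "trajectory", "channel",
              "water_shell", "score_table")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown synthetic kind {self.kind!r}")


def generate(spec: SyntheticSpec):
    """Dispatch a SyntheticSpec to its generator; returns (object, truth)."""
    p = dict(spec.parameters)
    if spec.kind == "dipeptide":
        return make_dipeptide_structure(p["sequence"], seed=spec.seed)
    if spec.kind == "trajectory":
        ref, _ = make_dipeptide_structure(p.pop("sequence", "DG"), seed=spec.seed)
        sigma = p.pop("per_atom_sigma", 0.5)
        if np.isscalar(sigma):
            sigma = np.full(ref.n_atoms, float(sigma))
        return make_trajectory(ref, sigma, p.pop("n_frames", 100),
                               p.pop("rigid_noise", False), seed=spec.seed, **p)
    if spec.kind == "channel":
        return make_channel_structure(p["radius_profile"],
                                      p.get("lining_density", 12), seed=spec.seed)
    if spec.kind == "score_table":
        return make_score_table(p["n"], p["fraction_pass_energy"],
                                p["fraction_pass_umami"], seed=spec.seed,
                                joint_fraction=p.get("joint_fraction"))
    if spec.kind == "toy_receptor":
        return make_toy_receptor(seed=spec.seed, **p)
    if spec.kind == "water_shell":
        return make_water_shell(seed=spec.seed, **p)
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# dipeptide structures


def make_dipeptide_structure(sequence: str, seed: int = 0):
    """All-atom 3-D dipeptide built from the sequence by seeded
    distance-geometry embedding over ideal bond lengths and angles.

    Free N-terminal amine and C-terminal carboxyl; Gasteiger partial charges
    attached.  Returns (StructureModel, truth dict).
    """
    seq = sequence.upper()
    for code in seq:
        if code not in STANDARD_AA:
            raise ValueError(f"unknown residue code {code!r} in {sequence!r}")
    if len(seq) != 2:
        raise ValueError("sequence must name exactly two residues")
    mol = Chem.MolFromSequence(seq)
    if mol is None:
        raise ValueError(f"could not build dipeptide {sequence!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2 ** 31 - 2) + 1
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise RuntimeError(f"embedding failed for {sequence!r}")
    AllChem.ComputeGasteigerCharges(mol)

    conf = mol.GetConformer()
    names, elements, res_names, res_numbers, charges = [], [], [], [], []
    h_counter: dict = {}
    for atom in mol.GetAtoms():
        info = atom.GetPDBResidueInfo()
        if info is not None:
            name = info.GetName().strip()
            res_name = info.GetResidueName().strip()
            res_num = info.GetResidueNumber()
        else:  # hydrogens added after sequence construction
            nb = atom.GetNeighbors()[0]
            nb_info = nb.GetPDBResidueInfo()
            res_name = nb_info.GetResidueName().strip()
            res_num = nb_info.GetResidueNumber()
            h_counter[res_num] = h_counter.get(res_num, 0) + 1
            name = f"H{h_counter[res_num]}"
        names.append(name)
        elements.append(atom.GetSymbol().upper())
        res_names.append(res_name)
        res_numbers.append(res_num)
        charges.append(float(atom.GetDoubleProp("_GasteigerCharge")))

    n = mol.GetNumAtoms()
    coords = np.array([list(conf.GetAtomPosition(i)) for i in range(n)])
    model = StructureModel(
        serials=np.arange(1, n + 1), names=names, elements=elements,
        res_names=res_names, res_numbers=res_numbers, chains=["A"] * n,
        coords=coords, charges=charges)
    truth = {
        "sequence": seq,
        "n_heavy_atoms": sum(1 for e in elements if e != "H"),
        "n_atoms": n,
    }
    return model, truth


# ---------------------------------------------------------------------------
# trajectories


def make_trajectory(reference: StructureModel, per_atom_sigma, n_frames: int,
                    rigid_noise: bool = False, seed: int = 0,
                    dt_ps: float = 10.0):
    """Reference plus isotropic Gaussian displacements (per-axis sigma_i).

    With ``rigid_noise`` each frame additionally receives a random global
    rotation and translation, exercising superposition removal.  Synthetic
    per-frame potential energies (Gaussian, seeded) are attached so
    lowest-energy representative selection is deterministic.
    Returns (Trajectory, truth dict with the planted sigma).
    """
    sigma = np.asarray(per_atom_sigma, dtype=float)
    if sigma.ndim == 0:
        sigma = np.full(reference.n_atoms, float(sigma))
    if len(sigma) != reference.n_atoms:
        raise ValueError("per_atom_sigma length must equal atom count")
    if (sigma < 0).any():
        raise ValueError("sigma must be non-negative")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")

    rng = np.random.default_rng(seed)
    frames = reference.coords[None] + rng.normal(
        size=(n_frames, reference.n_atoms, 3)) * sigma[None, :, None]
    if rigid_noise:
        rots = Rotation.random(n_frames, random_state=rng)
        shifts = rng.uniform(-10.0, 10.0, size=(n_frames, 3))
        center = reference.coords.mean(axis=0)
        for k in range(n_frames):
            frames[k] = rots[k].apply(frames[k] - center) + center + shifts[k]
    energies = rng.normal(loc=-1000.0, scale=25.0, size=n_frames)
    traj = Trajectory(topology=reference, coords=frames,
                      times=np.arange(n_frames) * dt_ps + dt_ps,
                      energies=energies)
    truth = {"sigma": sigma, "rigid_noise": rigid_noise,
             "energies": energies.copy()}
    return traj, truth


# ---------------------------------------------------------------------------
# channel fixtures


def make_channel_structure(radius_profile: Sequence[tuple], lining_density: int = 12,
                           seed: int = 0, element: str = "C",
                           residue_names: Sequence[str] | None = None):
    """Pseudo-atom rings along z whose maximal inscribed sphere at each
    profile station has the prescribed radius.

    radius_profile: (axial position Angstrom, pore radius Angstrom) pairs,
    positions strictly increasing, radii positive.  Each ring is one residue
    (GLY by default; override per-station with ``residue_names``).
    Returns (StructureModel, truth dict with the planted profile).
    """
    profile = [(float(z), float(r)) for z, r in radius_profile]
    if len(profile) < 2:
        raise ValueError("radius profile needs at least 2 stations")
    zs = [z for z, _ in profile]
    if any(b <= a for a, b in zip(zs, zs[1:])):
        raise ValueError("axial positions must be strictly increasing")
    if any(r <= 0 for _, r in profile):
        raise ValueError("pore radii must be positive")
    if residue_names is not None and len(residue_names) != len(profile):
        raise ValueError("residue_names must match the number of stations")

    rng = np.random.default_rng(seed)
    r_atom = vdw_radius(element)
    serials, names, elements, res_names, res_numbers, chains, coords = \
        [], [], [], [], [], [], []
    serial = 1
    for i, (z, r_pore) in enumerate(profile):
        phase = rng.uniform(0, 2 * np.pi)
        res = "GLY" if residue_names is None else residue_names[i]
        ring_r = r_pore + r_atom
        for j in range(lining_density):
            theta = phase + 2 * np.pi * j / lining_density
            coords.append([ring_r * np.cos(theta), ring_r * np.sin(theta), z])
            serials.append(serial)
            names.append(f"{element}{j + 1}")
            elements.append(element)
            res_names.append(res)
            res_numbers.append(i + 1)
            chains.append("A")
            serial += 1
    model = StructureModel(serials, names, elements, res_names, res_numbers,
                           chains, np.asarray(coords))
    radii = [r for _, r in profile]
    i_min = int(np.argmin(radii))
    truth = {
        "profile": profile,
        "min_radius": radii[i_min],
        "min_position": zs[i_min],
        "axis_start": np.array([0.0, 0.0, zs[0]]),
        "axis_end": np.array([0.0, 0.0, zs[-1]]),
    }
    return model, truth


# ---------------------------------------------------------------------------
# hydrogen-bond fixtures

_HB_BOUND_ACCEPTOR = np.array([2.9, 0.0, 0.0])   # d(N..O)=2.9 A, angle 180 deg
_HB_BROKEN_ACCEPTOR = np.array([6.0, 0.0, 0.0])  # distance criterion violated


def make_hbond_trajectory(occupancy: float, n_frames: int, seed: int = 0):
    """Donor-H...acceptor triad bonded in exactly round(occupancy*n_frames)
    frames (geometry: 2.9 Angstrom donor-acceptor, 180 degree angle) and
    broken otherwise (acceptor displaced to 6 Angstrom).

    Returns (Trajectory, truth dict with the planted bonded frame indices).
    """
    if not 0.0 <= occupancy <= 1.0:
        raise ValueError("occupancy must lie in [0, 1]")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    topo = StructureModel(
        serials=[1, 2, 3], names=["N", "H", "O"], elements=["N", "H", "O"],
        res_names=["ALA", "ALA", "SER"], res_numbers=[1, 1, 2],
        chains=["A", "A", "B"],
        coords=np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], _HB_BOUND_ACCEPTOR]))
    rng = np.random.default_rng(seed)
    k = int(round(occupancy * n_frames))
    bonded = np.sort(rng.choice(n_frames, size=k, replace=False))
    coords = np.repeat(topo.coords[None], n_frames, axis=0)
    mask = np.ones(n_frames, bool)
    mask[bonded] = False
    coords[mask, 2] = _HB_BROKEN_ACCEPTOR
    traj = Trajectory(topology=topo, coords=coords,
                      times=np.arange(n_frames) * 10.0 + 10.0)
    return traj, {"bonded_frames": bonded, "occupancy": k / n_frames}


# ---------------------------------------------------------------------------
# score tables


def make_score_table(n: int, fraction_pass_energy: float,
                     fraction_pass_umami: float, seed: int = 0,
                     joint_fraction: float | None = None):
    """Docking-energy / umami-probability table with exact planted pass
    fractions against the -6.5 kcal/mol and 85% thresholds.

    ``joint_fraction`` plants the overlap of the two pass sets; left None,
    the sets are drawn independently.  Both pockets (T1R1, T1R3) share the
    planted energy pass set (values drawn separately).
    Returns (pandas.DataFrame, truth dict with the planted pass lists).
    """
    import pandas as pd

    if not (0 <= fraction_pass_energy <= 1 and 0 <= fraction_pass_umami <= 1):
        raise ValueError("pass fractions must lie in [0, 1]")
    if n < 1 or n > 400:
        raise ValueError("n must be between 1 and 400")
    rng = np.random.default_rng(seed)
    k_e = int(round(fraction_pass_energy * n))
    k_u = int(round(fraction_pass_umami * n))
    perm = rng.permutation(n)
    if joint_fraction is None:
        energy_idx = set(perm[:k_e].tolist())
        umami_idx = set(rng.permutation(n)[:k_u].tolist())
    else:
        k_j = int(round(joint_fraction * n))
        if not max(0, k_e + k_u - n) <= k_j <= min(k_e, k_u):
            raise ValueError("joint_fraction incompatible with pass fractions")
        energy_idx = set(perm[:k_e].tolist())
        umami_idx = set(perm[:k_j].tolist()) | set(perm[k_e:k_e + k_u - k_j].tolist())

    seqs = enumerate_dipeptides()[:n]
    def draw_energy(passes):
        v = rng.uniform(-9.5, -6.6) if passes else rng.uniform(-6.4, -3.0)
        return round(v, 1)

    rows = []
    for i, seq in enumerate(seqs):
        e_pass = i in energy_idx
        u_pass = i in umami_idx
        prob = rng.uniform(0.86, 0.995) if u_pass else rng.uniform(0.30, 0.84)
        rows.append({
            "sequence": seq,
            "e_t1r1_kcal": draw_energy(e_pass),
            "e_t1r3_kcal": draw_energy(e_pass),
            "umami_prob": round(prob, 3),
        })
    table = pd.DataFrame(rows)
    truth = {
        "pass_energy": sorted(seqs[i] for i in energy_idx),
        "pass_umami": sorted(seqs[i] for i in umami_idx),
        "joint": sorted(seqs[i] for i in energy_idx & umami_idx),
    }
    return table, truth


# ---------------------------------------------------------------------------
# toy receptor and solvation fixtures


def make_toy_receptor(n_residues: int = 8, pocket_radius: float = 6.0,
                      seed: int = 0):
    """Ring of Calpha-only pseudo-residues around a central pocket.

    A minimal receptor for contact/pocket analyses: residues evenly spaced
    on a circle of the given radius in the xy plane, alternating hydrophobic
    (LEU) and acidic (GLU) identities.  Returns (StructureModel, truth).
    """
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0, 2 * np.pi)
    names, elements, res_names, res_numbers, chains, coords = [], [], [], [], [], []
    for i in range(n_residues):
        theta = phase + 2 * np.pi * i / n_residues
        coords.append([pocket_radius * np.cos(theta),
                       pocket_radius * np.sin(theta), 0.0])
        names.append("CA")
        elements.append("C")
        res_names.append("LEU" if i % 2 == 0 else "GLU")
        res_numbers.append(i + 1)
        chains.append("A")
    model = StructureModel(np.arange(1, n_residues + 1), names, elements,
                           res_names, res_numbers, chains, np.asarray(coords))
    return model, {"pocket_center": np.zeros(3), "pocket_radius": pocket_radius}


def make_water_shell(center, n_near: int, n_far: int, near_radius: float = 3.0,
                     far_radius: float = 20.0, seed: int = 0,
                     start_residue: int = 1000, chain: str = "W"):
    """Water-oxygen pseudo-atoms: n_near on a shell close to center, n_far on
    a distant shell.  Returns (StructureModel, truth with the near count)."""
    rng = np.random.default_rng(seed)
    center = np.asarray(center, dtype=float)

    def shell(n, radius):
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        return center + radius * v

    coords = np.vstack([shell(n_near, near_radius), shell(n_far, far_radius)])
    n = n_near + n_far
    model = StructureModel(
        serials=np.arange(1, n + 1), names=["O"] * n, elements=["O"] * n,
        res_names=["HOH"] * n,
        res_numbers=np.arange(start_residue, start_residue + n),
        chains=[chain] * n, coords=coords)
    return model, {"n_near": n_near}


def write_truth_sidecar(truth: dict, path) -> None:
    """Record planted ground truth next to a written artifact as JSON."""
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"not JSON-serializable: {type(o)}")
    Path(path).write_text(json.dumps(truth, indent=2, default=default, sort_keys=True))
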