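"""Trajectory analytics: RMSD series, per-residue RMSF, flexibility
correlation, RMSD-threshold conformational clustering, snapshot accounting.

All distances are handled internally in Angstrom; the clustering threshold is
accepted in nm (the unit the field quotes it in) and converted at the
interface.  RMSD is mass-unweighted:

    RMSD = sqrt( (1/N) * sum_i |delta_i|^2 )

with delta_i the displacement of atom i after least-squares superposition.
Clustering uses the pairwise criterion C = 1 iff RMSD <= threshold, grouped
by deterministic greedy leader assignment in frame order; each cluster's
representative is its lowest-potential-energy frame (ties broken by the
lowest frame index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .structure import StructureModel, Trajectory, kabsch_superpose

__all__ = [
    "ClusterResult", "FlexibilityProfile", "rmsd_series", "rmsf_profile",
    "flexibility_correlation", "cluster_threshold", "snapshot_count",
]

NM_PER_ANGSTROM = 0.1


@dataclass
class FlexibilityProfile:
    """Per-residue RMSF (Angstrom) over a named atom selection."""

    rmsf: dict  # (chain, residue_number, residue_name) -> RMSF in Angstrom
    selection: str = "CA"

    def values_nm(self) -> dict:
        return {k: v * NM_PER_ANGSTROM for k, v in self.rmsf.items()}


@dataclass
class ClusterResult:
    """Frame partition under the RMSD-threshold criterion.

    labels[i] is the cluster id of frame i; representatives maps cluster id to
    the index of its minimum-energy member; seeds maps cluster id to the frame
    that founded it (against which membership was tested).
    """

    threshold_nm: float
    labels: np.ndarray
    representatives: dict
    seeds: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)


def _superposed(frame, reference, selection):
    rot, trans, rmsd = kabsch_superpose(frame, reference, selection)
    return rmsd


def rmsd_series(traj: Trajectory, reference=None, selection=None) -> np.ndarray:
    """Per-frame RMSD (Angstrom) to a reference after Kabsch superposition.

    ``reference`` defaults to frame 0; ``selection`` is an atom-index array
    (all atoms when None).
    """
    ref = traj.coords[0] if reference is None else np.asarray(reference, float)
    if ref.shape != traj.coords.shape[1:]:
        raise ValueError("reference must match the trajectory's atom count")
    sel = (np.arange(traj.topology.n_atoms) if selection is None
           else np.asarray(selection, dtype=int))
    if len(sel) == 0:
        raise ValueError("selection is empty")
    return np.array([_superposed(traj.coords[k], ref, sel)
                     for k in range(traj.n_frames)])


def _mean_superposed_coords(coords, sel, n_iter=2):
    """Superpose all frames onto their running mean (iterated) and return the
    fitted coordinates restricted to the selection."""
    fitted = coords[:, sel, :].copy()
    reference = fitted[0]
    for _ in range(n_iter):
        for k in range(len(fitted)):
            rot, trans, _ = kabsch_superpose(fitted[k], reference)
            fitted[k] = fitted[k] @ rot.T + trans
        reference = fitted.mean(axis=0)
    return fitted


def rmsf_profile(traj: Trajectory, selection=None, atom_name: str = "CA",
                 superpose: bool = True) -> FlexibilityProfile:
    """Per-residue RMSF about the trajectory mean structure.

    Frames are superposed to their mean (two iterations), then
    RMSF_i = sqrt(<|r_i - <r_i>|^2>).  The selection defaults to Calpha
    atoms; pass explicit indices to override.  ``superpose=False`` skips the
    fit for trajectories already sharing a frame (the fit removes six
    rigid-body degrees of freedom, slightly deflating the RMSF of small
    selections).
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    topo = traj.topology
    if selection is None:
        sel = topo.select(name=atom_name)
        if len(sel) < 3:  # small-molecule topologies lack a usable CA set
            sel = np.arange(topo.n_atoms)
    else:
        sel = np.asarray(selection, dtype=int)
    fitted = (_mean_superposed_coords(traj.coords, sel) if superpose
              else traj.coords[:, sel, :])
    mean = fitted.mean(axis=0)
    rmsf = np.sqrt(((fitted - mean) ** 2).sum(axis=2).mean(axis=0))
    keys = [(topo.chains[i], int(topo.res_numbers[i]), topo.res_names[i])
            for i in sel]
    profile = {}
    for key, value in zip(keys, rmsf):
        profile.setdefault(key, []).append(float(value))
    # residues contributing several selected atoms report their mean RMSF
    return FlexibilityProfile(
        rmsf={k: float(np.mean(v)) for k, v in profile.items()},
        selection=atom_name if selection is None else "custom")


def flexibility_correlation(profile_a: FlexibilityProfile,
                            profile_b: FlexibilityProfile):
    """Pearson R and least-squares slope k of profile_b on profile_a over the
    shared residue keys.  Returns (R, k, shared_keys)."""
    shared = sorted(set(profile_a.rmsf) & set(profile_b.rmsf))
    if len(shared) < 3:
        raise ValueError("profiles share fewer than 3 residues")
    a = np.array([profile_a.rmsf[k] for k in shared])
    b = np.array([profile_b.rmsf[k] for k in shared])
    r = float(stats.pearsonr(a, b).statistic)
    slope = float(np.polyfit(a, b, 1)[0])
    return r, slope, shared


def cluster_threshold(traj: Trajectory, threshold_nm: float = 0.5,
                      selection=None, atom_name: str = "CA") -> ClusterResult:
    """Greedy leader clustering of frames under the RMSD criterion.

    In frame order, each frame joins the first existing cluster whose seed
    frame lies within the threshold (pairwise Calpha RMSD after
    superposition), otherwise it founds a new cluster.  Representatives are
    the minimum-energy members (uniform energies assumed when the trajectory
    carries none, so ties fall to the lowest frame index).
    """
    if threshold_nm <= 0:
        raise ValueError("threshold must be positive")
    threshold = threshold_nm / NM_PER_ANGSTROM
    topo = traj.topology
    if selection is None:
        sel = topo.select(name=atom_name)
        if len(sel) < 3:
            sel = np.arange(topo.n_atoms)
    else:
        sel = np.asarray(selection, dtype=int)

    labels = np.full(traj.n_frames, -1, dtype=int)
    seeds: dict = {}
    for k in range(traj.n_frames):
        for cid, seed_frame in seeds.items():
            if _superposed(traj.coords[k], traj.coords[seed_frame], sel) <= threshold:
                labels[k] = cid
                break
        else:
            cid = len(seeds)
            seeds[cid] = k
            labels[k] = cid

    energies = (traj.energies if traj.energies is not None
                else np.zeros(traj.n_frames))
    representatives = {}
    for cid in seeds:
        members = np.nonzero(labels == cid)[0]
        representatives[cid] = int(members[np.argmin(energies[members])])
    return ClusterResult(threshold_nm=threshold_nm, labels=labels,
                         representatives=representatives, seeds=seeds)


def snapshot_count(duration_ns: float, save_interval_steps: int,
                   timestep_fs: float) -> int:
    """Number of snapshots from a run of the given length sampled every
    ``save_interval_steps`` integration steps."""
    if duration_ns <= 0 or save_interval_steps <= 0 or timestep_fs <= 0:
        raise ValueError("all arguments must be positive")
    duration_fs = duration_ns * 1e6
    return int(duration_fs // (save_interval_steps * timestep_fs))
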