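"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from umamidyn.structure import StructureModel


# ---------------------------------------------------------------------------
# oracles


def quaternion_grid_rmsd(mobile: np.ndarray, reference: np.ndarray,
                         n_coarse: int = 4000, n_levels: int = 24) -> float:
    """Brute-force minimum RMSD over rotations: seeded coarse quaternion
    sampling followed by shrinking axis-angle grid refinement.  Independent
    of any analytic superposition routine."""
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)
    n = len(mob)

    def rmsd_of(rot: Rotation) -> float:
        return float(np.sqrt(((rot.apply(mob) - ref) ** 2).sum() / n))

    rng = np.random.default_rng(12345)
    quats = rng.normal(size=(n_coarse, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    best_rot = None
    best = np.inf
    for q in quats:
        r = Rotation.from_quat(q)
        v = rmsd_of(r)
        if v < best:
            best, best_rot = v, r
    delta = 0.4  # radians, shrinks geometrically
    axes = np.array([[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1)
                     for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)], float)
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    for _ in range(n_levels):
        improved = False
        for ax in axes:
            cand = Rotation.from_rotvec(delta * ax) * best_rot
            v = rmsd_of(cand)
            if v < best:
                best, best_rot, improved = v, cand, True
        if not improved:
            delta *= 0.5
    return best


def plane_grid_channel_radius(coords: np.ndarray, radii: np.ndarray,
                              point: np.ndarray, axis_unit: np.ndarray,
                              half_extent: float = 3.0,
                              step: float = 0.05) -> float:
    """Brute-force maximal inscribed-sphere radius in the plane through
    ``point`` perpendicular to ``axis_unit``: exhaustive grid search."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis_unit @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis_unit, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis_unit, e1)
    ticks = np.arange(-half_extent, half_extent + step / 2, step)
    best = -np.inf
    for a in ticks:
        centers = point + a * e1 + ticks[:, None] * e2
        d = np.linalg.norm(coords[None, :, :] - centers[:, None, :], axis=2)
        clearance = (d - radii[None, :]).min(axis=1)
        best = max(best, clearance.max())
    return float(best)


def make_hbond_triad(distance: float, angle_deg: float) -> StructureModel:
    """Donor-H-acceptor triad with prescribed donor-acceptor distance and
    acceptor-hydrogen-donor angle (vertex at the hydrogen)."""
    theta = np.radians(angle_deg)
    h = np.array([1.0, 0.0, 0.0])
    u = np.array([np.cos(np.pi - theta), np.sin(np.pi - theta), 0.0])

    def gap(t):
        a = h + t * u
        return np.linalg.norm(a) - distance

    t = brentq(gap, 0.05, distance + 3.0)
    acceptor = h + t * u
    return StructureModel(
        serials=[1, 2, 3], names=["N", "H", "O"], elements=["N", "H", "O"],
        res_names=["ALA", "ALA", "SER"], res_numbers=[1, 1, 2],
        chains=["A", "A", "B"],
        coords=np.array([[0.0, 0.0, 0.0], h, acceptor]))


def simple_model(coords, elements=None, res_names=None, res_numbers=None,
                 chains=None, names=None, charges=None, vdw=None):
    """Compact StructureModel builder for geometric fixtures."""
    coords = np.asarray(coords, float)
    n = len(coords)
    elements = elements or ["C"] * n
    return StructureModel(
        serials=np.arange(1, n + 1),
        names=names or [f"{elements[i]}{i + 1}" for i in range(n)],
        elements=elements,
        res_names=res_names or ["LIG"] * n,
        res_numbers=res_numbers if res_numbers is not None else np.arange(1, n + 1),
        chains=chains or ["A"] * n,
        coords=coords, vdw=vdw, charges=charges)


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def dg_structure():
    from umamidyn.synthetic import make_dipeptide_structure
    model, truth = make_dipeptide_structure("DG", seed=1)
    return model, truth


@pytest.fixture(scope="session")
def gg_structure():
    from umamidyn.synthetic import make_dipeptide_structure
    model, truth = make_dipeptide_structure("GG", seed=1)
    return model, truth
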