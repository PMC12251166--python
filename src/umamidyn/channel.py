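"""HOLE-style channel profiling: maximal inscribed-sphere radius along an
axis at 0.25 Angstrom stations, nearest contact residues, and channel-level
acid-base summaries.

At each station the sphere center is confined to the plane perpendicular to
the user-supplied axis and optimized (seeded multi-start + Nelder-Mead) to
maximize the clearance  r(c) = min_i (|c - x_i| - vdw_i).  Stations whose
clearance exceeds a bulk cap are flagged open to solvent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .params import TITRATABLE_RESIDUES
from .structure import StructureModel

__all__ = ["ChannelProfile", "ChannelAciditySummary", "profile_channel",
           "channel_acidity", "suggest_axis"]

STATION_SPACING = 0.25  # Angstrom
BULK_RADIUS = 10.0      # Angstrom: pore considered open to solvent
NEIGHBOR_CUTOFF = 15.0  # Angstrom: atoms considered per station


@dataclass
class ChannelProfile:
    """Radius profile along the channel axis.

    stations: axial coordinate (Angstrom, 0.25 spacing) from axis_start;
    radius: maximal inscribed-sphere radius per station; centers: sphere
    centers; contacts: the two nearest contact residues per station as
    (chain, residue_number, residue_name); open_to_bulk: stations where the
    clearance reached the bulk cap.
    """

    stations: np.ndarray
    radius: np.ndarray
    centers: np.ndarray
    contacts: list
    open_to_bulk: np.ndarray
    axis_start: np.ndarray
    axis_end: np.ndarray

    @property
    def min_radius(self) -> float:
        return float(self.radius[~self.open_to_bulk].min())

    @property
    def min_station(self) -> float:
        closed = np.where(~self.open_to_bulk)[0]
        return float(self.stations[closed[np.argmin(self.radius[closed])]])

    @property
    def mean_radius(self) -> float:
        return float(self.radius[~self.open_to_bulk].mean())

    def contact_residue_set(self) -> set:
        out = set()
        for pair in self.contacts:
            out.update(pair)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, r, c, pair, open_ in zip(self.stations, self.radius,
                                        self.centers, self.contacts,
                                        self.open_to_bulk):
            rows.append({
                "station": float(s), "radius": float(r),
                "x": c[0], "y": c[1], "z": c[2],
                "contact1": "/".join(map(str, pair[0])) if len(pair) > 0 else "",
                "contact2": "/".join(map(str, pair[1])) if len(pair) > 1 else "",
                "open_to_bulk": bool(open_),
            })
        return pd.DataFrame(rows)


@dataclass
class ChannelAciditySummary:
    """Mean model pKa over the unique titratable contact residues."""

    assignments: dict  # (chain, residue_number, residue_name) -> pKa
    mean_pka: float | None
    classification: str  # "basic" | "acidic" | "undefined"


def _clearance(center, coords, radii):
    return float((np.linalg.norm(coords - center, axis=1) - radii).min())


def profile_channel(model: StructureModel, axis_start, axis_end,
                    seed: int = 0, spacing: float = STATION_SPACING,
                    bulk_radius: float = BULK_RADIUS,
                    n_starts: int = 16) -> ChannelProfile:
    """Profile the maximal inscribed-sphere radius along the axis.

    The axis endpoints are user-supplied (see ``suggest_axis``); stations are
    laid every ``spacing`` Angstrom.  In each station plane the center is
    optimized from ``n_starts`` seeded multi-starts around the previous
    station's optimum.
    """
    start = np.asarray(axis_start, dtype=float)
    end = np.asarray(axis_end, dtype=float)
    axis = end - start
    length = np.linalg.norm(axis)
    if length < 1e-6:
        raise ValueError("axis endpoints must be distinct")
    u = axis / length
    # in-plane orthonormal basis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(u @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)

    rng = np.random.default_rng(seed)
    n_stations = int(np.floor(length / spacing)) + 1
    stations = np.arange(n_stations) * spacing

    radius = np.zeros(n_stations)
    centers = np.zeros((n_stations, 3))
    contacts: list = []
    open_to_bulk = np.zeros(n_stations, bool)
    prev_inplane = np.zeros(2)

    for k, s in enumerate(stations):
        p0 = start + s * u
        d_axis = np.linalg.norm(model.coords - p0, axis=1)
        near = np.nonzero(d_axis < NEIGHBOR_CUTOFF)[0]
        if len(near) == 0:
            radius[k] = bulk_radius
            centers[k] = p0
            open_to_bulk[k] = True
            contacts.append(())
            prev_inplane = np.zeros(2)
            continue
        coords = model.coords[near]
        radii = model.vdw[near]

        def neg_clearance(xy):
            c = p0 + xy[0] * e1 + xy[1] * e2
            return -_clearance(c, coords, radii)

        best_xy, best_val = prev_inplane, neg_clearance(prev_inplane)
        starts = [prev_inplane]
        angles = rng.uniform(0, 2 * np.pi, n_starts)
        ring = rng.uniform(0.5, 2.0, n_starts)
        for a, rr in zip(angles, ring):
            starts.append(prev_inplane + rr * np.array([np.cos(a), np.sin(a)]))
        for x0 in starts:
            res = minimize(neg_clearance, x0, method="Nelder-Mead",
                           options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400})
            if res.fun < best_val:
                best_val, best_xy = res.fun, res.x
        r = -best_val
        center = p0 + best_xy[0] * e1 + best_xy[1] * e2
        if r >= bulk_radius:
            r = bulk_radius
            open_to_bulk[k] = True
        radius[k] = r
        centers[k] = center
        prev_inplane = best_xy

        surf = np.linalg.norm(coords - center, axis=1) - radii
        order = np.argsort(surf)
        pair = []
        seen_res = set()
        for j in order:
            i = near[j]
            key = (model.chains[i], int(model.res_numbers[i]), model.res_names[i])
            if key in seen_res:
                continue
            seen_res.add(key)
            pair.append(key)
            if len(pair) == 2:
                break
        contacts.append(tuple(pair))

    return ChannelProfile(stations=stations, radius=radius, centers=centers,
                          contacts=contacts, open_to_bulk=open_to_bulk,
                          axis_start=start, axis_end=end)


def channel_acidity(profile: ChannelProfile, pka_source=None
                    ) -> ChannelAciditySummary:
    """Mean pKa over the unique titratable contact residues of a profile.

    ``pka_source`` maps (chain, residue_number, residue_name) or residue name
    to a pKa; the model side-chain table is the default.  A channel with mean
    pKa above 7 is labeled basic, below acidic.
    """
    assignments = {}
    for key in sorted(profile.contact_residue_set()):
        res_name = key[2]
        if pka_source is not None and key in pka_source:
            assignments[key] = float(pka_source[key])
        elif pka_source is not None and res_name in pka_source:
            assignments[key] = float(pka_source[res_name])
        elif pka_source is None and res_name in TITRATABLE_RESIDUES:
            assignments[key] = TITRATABLE_RESIDUES[res_name]
    if not assignments:
        return ChannelAciditySummary({}, None, "undefined")
    mean = float(np.mean(list(assignments.values())))
    return ChannelAciditySummary(assignments, mean,
                                 "basic" if mean > 7.0 else "acidic")


def suggest_axis(model: StructureModel, selection=None):
    """Heuristic axis endpoints: the extreme projections of the (selected)
    atoms onto their first principal axis, through the centroid."""
    sel = (np.arange(model.n_atoms) if selection is None
           else np.asarray(selection, dtype=int))
    xyz = model.coords[sel]
    centered = xyz - xyz.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    proj = centered @ axis
    centroid = xyz.mean(axis=0)
    return centroid + proj.min() * axis, centroid + proj.max() * axis
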