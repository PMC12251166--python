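"""Dipeptide database construction and physicochemical screening.

Enumerates the 400 ordered pairs of the 20 standard amino acids, computes
molecular weight, Henderson-Hasselbalch net charge, isoelectric point and
hydropathy for each, and applies the virtual-screening filters (docking
energy below -6.5 kcal/mol, umami probability above 85%, acidic/hydrophilic
classification).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import protein_weights

from .params import (
    ACIDIC_SIDECHAINS,
    BASIC_SIDECHAINS,
    DEFAULT_PKA,
    KYTE_DOOLITTLE,
    STANDARD_AA,
    PKaTable,
)

WATER_MASS = 18.0153  # Da, average

#: screening thresholds (kcal/mol and probability fraction)
ENERGY_THRESHOLD = -6.5
UMAMI_THRESHOLD = 0.85

__all__ = [
    "enumerate_dipeptides", "molecular_weight", "net_charge",
    "isoelectric_point", "hydrophobicity", "build_database",
    "attach_scores", "screen", "ScreenResult",
]


def _validate(sequence: str) -> str:
    seq = sequence.upper()
    if len(seq) != 2:
        raise ValueError(f"dipeptide sequence must have length 2, got {sequence!r}")
    for code in seq:
        if code not in STANDARD_AA:
            raise ValueError(f"unknown residue code {code!r} in {sequence!r}")
    return seq


def enumerate_dipeptides() -> list[str]:
    """All 20x20 ordered dipeptide sequences, lexicographically sorted."""
    return ["".join(p) for p in itertools.product(sorted(STANDARD_AA), repeat=2)]


def molecular_weight(sequence: str) -> float:
    """Average molecular weight (Da): free amino acids minus one water."""
    seq = _validate(sequence)
    return sum(protein_weights[c] for c in seq) - WATER_MASS


def _ionizable_groups(seq: str, table: PKaTable) -> list[tuple[float, int]]:
    """(pKa, sign) pairs; sign is the group's charge when protonated (+1)
    or deprotonated (-1)."""
    groups = [(table.n_terminus, +1), (table.c_terminus, -1)]
    for code in seq:
        if code in BASIC_SIDECHAINS:
            groups.append((table.sidechains[code], +1))
        elif code in ACIDIC_SIDECHAINS:
            groups.append((table.sidechains[code], -1))
    return groups


def net_charge(sequence: str, pH: float, table: PKaTable = DEFAULT_PKA) -> float:
    """Henderson-Hasselbalch net charge at the given pH (elementary charges).

    Basic groups contribute 1/(1+10^(pH-pKa)); acidic groups contribute
    -1/(1+10^(pKa-pH)).  Only the two termini and titratable side chains
    are considered ionizable (free, uncapped dipeptide).
    """
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH must be in [0, 14], got {pH}")
    seq = _validate(sequence)
    q = 0.0
    for pka, sign in _ionizable_groups(seq, table):
        q += sign / (1.0 + 10.0 ** (sign * (pH - pka)))
    return q


def isoelectric_point(
    sequence: str, table: PKaTable = DEFAULT_PKA, tol: float = 1e-3
) -> float:
    """pH at which the net charge vanishes, by bisection on (0, 14).

    The net charge is strictly decreasing in pH, so the root is unique;
    every dipeptide carries both termini, so a sign change always exists.
    """
    seq = _validate(sequence)
    lo, hi = 1e-6, 14.0 - 1e-6
    f_lo = net_charge(seq, lo, table)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        f_mid = net_charge(seq, mid, table)
        if (f_lo > 0) == (f_mid > 0):
            lo, f_lo = mid, f_mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def hydrophobicity(
    sequence: str, scale: Mapping[str, float] | None = None
) -> float:
    """Summed per-residue hydropathy (Kyte-Doolittle by default)."""
    seq = _validate(sequence)
    scale = KYTE_DOOLITTLE if scale is None else scale
    try:
        return sum(scale[c] for c in seq)
    except KeyError as exc:
        raise ValueError(f"hydropathy scale missing residue {exc.args[0]!r}") from None


def build_database(
    table: PKaTable = DEFAULT_PKA, scale: Mapping[str, float] | None = None
) -> pd.DataFrame:
    """DataFrame of all 400 dipeptides with computed properties and flags.

    Columns: sequence, mw_da, pi, net_charge_ph7, hydrophobicity, acidic,
    hydrophilic (plus score columns once attach_scores is applied).
    """
    rows = []
    for seq in enumerate_dipeptides():
        pi = isoelectric_point(seq, table)
        rows.append({
            "sequence": seq,
            "mw_da": molecular_weight(seq),
            "pi": pi,
            "net_charge_ph7": net_charge(seq, 7.0, table),
            "hydrophobicity": hydrophobicity(seq, scale),
        })
    df = pd.DataFrame(rows)
    df["acidic"] = df["pi"] < 7.0
    df["hydrophilic"] = df["hydrophobicity"] < 0.0
    return df


def attach_scores(database: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Left-join imported docking energies / umami probabilities onto the
    database by sequence.  Expected score columns (any subset):
    e_t1r1_kcal, e_t1r3_kcal, umami_prob."""
    known = {"sequence", "e_t1r1_kcal", "e_t1r3_kcal", "umami_prob"}
    cols = [c for c in scores.columns if c in known]
    if "sequence" not in cols:
        raise ValueError("score table must carry a 'sequence' column")
    return database.merge(scores[cols], on="sequence", how="left")


@dataclass
class ScreenResult:
    """Outcome of the physicochemical + docking + umami screen."""

    pass_energy_t1r1: set = field(default_factory=set)
    pass_energy_t1r3: set = field(default_factory=set)
    pass_umami: set = field(default_factory=set)
    joint: set = field(default_factory=set)
    acidic_hydrophilic: set = field(default_factory=set)
    n_missing_energy_t1r1: int = 0
    n_missing_energy_t1r3: int = 0
    n_missing_umami: int = 0
    summary: pd.DataFrame | None = None


def _passes_energy(values: pd.Series, threshold: float) -> pd.Series:
    # docking energies are reported at 0.1 kcal/mol precision
    return values.round(1) <= threshold + 1e-9


def screen(
    records: pd.DataFrame,
    energy_threshold: float = ENERGY_THRESHOLD,
    umami_threshold: float = UMAMI_THRESHOLD,
) -> ScreenResult:
    """Apply the screening filters and tabulate pass sets and fractions.

    Records lacking a score are excluded from that filter and counted
    separately; the joint set intersects every filter that has data.
    """
    res = ScreenResult()
    df = records
    n = len(df)
    seqs = df["sequence"] if "sequence" in df else pd.Series(range(n), name="sequence")

    filters = {}
    for col, attr, missing_attr, passfun in (
        ("e_t1r1_kcal", "pass_energy_t1r1", "n_missing_energy_t1r1",
         lambda v: _passes_energy(v, energy_threshold)),
        ("e_t1r3_kcal", "pass_energy_t1r3", "n_missing_energy_t1r3",
         lambda v: _passes_energy(v, energy_threshold)),
        ("umami_prob", "pass_umami", "n_missing_umami",
         lambda v: v >= umami_threshold - 1e-12),
    ):
        if col in df.columns:
            have = df[col].notna()
            setattr(res, missing_attr, int((~have).sum()))
            mask = have & passfun(df[col])
            passing = set(seqs[mask])
            setattr(res, attr, passing)
            filters[col] = passing

    if filters:
        res.joint = set.intersection(*filters.values())

    if {"acidic", "hydrophilic"} <= set(df.columns):
        mask = df["acidic"] & df["hydrophilic"]
        res.acidic_hydrophilic = set(seqs[mask])

    # fractions are quoted over the records actually carrying the score(s)
    n_scored = {
        "energy_t1r1": n - res.n_missing_energy_t1r1,
        "energy_t1r3": n - res.n_missing_energy_t1r3,
        "umami": n - res.n_missing_umami,
        "acidic_hydrophilic": n,
    }
    n_scored["joint"] = (min(n_scored[k] for k in
                             ("energy_t1r1", "energy_t1r3", "umami"))
                         if filters else 0)
    rows = []
    for name, passing in (
        ("energy_t1r1", res.pass_energy_t1r1),
        ("energy_t1r3", res.pass_energy_t1r3),
        ("umami", res.pass_umami),
        ("joint", res.joint),
        ("acidic_hydrophilic", res.acidic_hydrophilic),
    ):
        base = n_scored.get(name, n)
        rows.append({
            "filter": name,
            "count": len(passing),
            "n_scored": base,
            "fraction": len(passing) / base if base else 0.0,
        })
    res.summary = pd.DataFrame(rows)
    return res
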