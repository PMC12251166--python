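"""Shared parameter tables: pKa sets, hydropathy scales, van der Waals radii,
Lennard-Jones parameters.

All tables are plain data and user-overridable; the defaults are the package's
documented choices (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.SeqUtils.ProtParamData import kd as _KYTE_DOOLITTLE

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: three-letter <-> one-letter residue code maps for the 20 standard residues
THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: residues whose side chain is positively charged when protonated
BASIC_SIDECHAINS = frozenset("HKR")
#: residues whose side chain is negatively charged when deprotonated
ACIDIC_SIDECHAINS = frozenset("DECY")


@dataclass(frozen=True)
class PKaTable:
    """pKa values for the ionizable groups of free dipeptides.

    ``n_terminus``/``c_terminus`` are the alpha-amino and alpha-carboxyl
    groups; ``sidechains`` maps one-letter codes of the seven titratable side
    chains (D, E, H, C, Y, K, R).  The sign convention (which groups are
    positive when protonated) is fixed by residue identity, not stored here.
    """

    n_terminus: float = 8.6
    c_terminus: float = 3.6
    sidechains: dict = field(default_factory=lambda: {
        "D": 3.9, "E": 4.1, "H": 6.5, "C": 8.5,
        "Y": 10.1, "K": 10.8, "R": 12.5,
    })

    def __post_init__(self):
        values = [self.n_terminus, self.c_terminus, *self.sidechains.values()]
        if not all(0.0 < v < 14.0 for v in values):
            raise ValueError("pKa values must lie in (0, 14)")
        missing = (BASIC_SIDECHAINS | ACIDIC_SIDECHAINS) - set(self.sidechains)
        if missing:
            raise ValueError(f"pKa table missing side chains: {sorted(missing)}")


DEFAULT_PKA = PKaTable()

#: Kyte-Doolittle hydropathy scale (positive = hydrophobic), via Biopython
KYTE_DOOLITTLE: dict = dict(_KYTE_DOOLITTLE)

#: van der Waals radii (Angstrom) by element symbol (Bondi-style defaults)
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
DEFAULT_VDW = 1.70  # fallback for unlisted elements


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW)


#: Lennard-Jones well depth epsilon (kcal/mol) and sigma (Angstrom) per
#: element, Amber-ff-style generic atom values (Rmin/2 converted to sigma).
_RMIN2 = {"H": 0.60, "C": 1.9080, "N": 1.8240, "O": 1.6612, "S": 2.0000, "P": 2.1000}
_EPS = {"H": 0.0157, "C": 0.1094, "N": 0.1700, "O": 0.2100, "S": 0.2500, "P": 0.2000}
_RMIN2_TO_SIGMA = 2.0 / 2.0 ** (1.0 / 6.0)

LJ_TABLE = {
    el: (_EPS[el], _RMIN2[el] * _RMIN2_TO_SIGMA) for el in _RMIN2
}


def lj_parameters(element: str) -> tuple[float, float]:
    """(epsilon kcal/mol, sigma Angstrom) for an element; KeyError names it."""
    el = element.upper()
    if el not in LJ_TABLE:
        raise KeyError(f"no Lennard-Jones parameters for element {element!r}")
    return LJ_TABLE[el]


#: Coulomb constant, kcal/mol * Angstrom / e^2
COULOMB_CONSTANT = 332.0636

#: model side-chain pKa used for channel acidity summaries, by 3-letter code
TITRATABLE_RESIDUES = {
    "ASP": 3.9, "GLU": 4.1, "HIS": 6.5, "CYS": 8.5,
    "TYR": 10.1, "LYS": 10.8, "ARG": 12.5,
}
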