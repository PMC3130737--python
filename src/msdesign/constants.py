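"""Amino-acid tables used by the bead-rotamer model.

Side-chain heavy-atom counts and the Kyte-Doolittle hydropathy scale are
taken from the standard references; both are exact integers / published
values, with no fitted constants.
"""

from __future__ import annotations

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Number of side-chain heavy atoms (non-hydrogen atoms beyond the backbone).
SIDECHAIN_HEAVY_ATOMS: dict[str, int] = {
    "G": 0, "A": 1, "S": 2, "C": 2, "T": 3, "V": 3, "P": 3,
    "L": 4, "I": 4, "N": 4, "D": 4, "M": 4,
    "E": 5, "K": 5, "Q": 5, "H": 6, "F": 7, "R": 7, "Y": 8, "W": 10,
}

#: Kyte-Doolittle hydropathy index (J. Mol. Biol. 157:105, 1982).
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Hydrophobicity normalised to [-1, 1] (Kyte-Doolittle / 4.5).
HYDROPHOBICITY: dict[str, float] = {
    aa: KYTE_DOOLITTLE[aa] / 4.5 for aa in AMINO_ACIDS
}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}
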