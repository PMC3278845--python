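"""Fixed alphabets and atomic constants used across the package.

Column/row orders are frozen here once and imported everywhere:
amino acids in one-letter alphabetical order (ACDEFGHIKLMNPQRSTVWY)
and the 16 dinucleotide classes in alphabetical order (AA ... UU).
"""

from __future__ import annotations

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}

RNA_BASES: str = "ACGU"

#: The 16 dinucleotide classes, 5'->3', alphabetical: AA, AC, ..., UU.
DINUCLEOTIDES: tuple[str, ...] = tuple(b1 + b2 for b1 in RNA_BASES for b2 in RNA_BASES)
DINUC_INDEX: dict[str, int] = {d: i for i, d in enumerate(DINUCLEOTIDES)}
N_DINUC: int = 16

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

PROTEIN_RESNAMES = set(THREE_TO_ONE) | {"MSE", "UNK"}
RNA_RESNAMES = {"A", "C", "G", "U", "RA", "RC", "RG", "RU"}
DNA_RESNAMES = {"DA", "DC", "DG", "DT", "DU", "DI"}
SOLVENT_RESNAMES = {"HOH", "WAT", "DOD"}

#: Heavy-atom van der Waals radii (Angstrom) in the NACCESS tradition;
#: hydrogens are excluded from surface-area calculations.
VDW_RADII: dict[str, float] = {
    "C": 1.87,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "P": 1.90,
}

#: Default solvent probe radius in Angstrom (water).
PROBE_RADIUS: float = 1.4

#: Atom-atom distance (Angstrom) below which (strictly) a contact is scored.
CONTACT_CUTOFF: float = 3.5
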