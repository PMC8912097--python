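"""Per-residue property tables used by the feature calculators.

All tables are keyed by the 20 canonical one-letter amino-acid codes and are
pluggable: every consumer accepts an alternative mapping, so a different
hydrophobicity scale or pKa set can be swapped in without touching code.
Table identities are recorded here so derived features are reproducible.
"""

from __future__ import annotations

#: Canonical alphabet in the fixed order used everywhere (index encoding,
#: composition vectors, PAAC): alphabetical one-letter codes.
ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"

AA_TO_INDEX: dict[str, int] = {aa: i + 1 for i, aa in enumerate(ALPHABET)}
INDEX_TO_AA: dict[int, str] = {i: aa for aa, i in AA_TO_INDEX.items()}

#: Kyte & Doolittle (1982) hydropathy. Positive = hydrophobic.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}

#: Hopp & Woods (1981) hydrophilicity. Positive = hydrophilic.
HOPP_WOODS: dict[str, float] = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5,
    "G": 0.0, "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8,
    "M": -1.3, "N": 0.2, "P": 0.0, "Q": 0.2, "R": 3.0,
    "S": 0.3, "T": -0.4, "V": -1.5, "W": -3.4, "Y": -2.3,
}

#: Side-chain mass in Daltons (glycine side chain = H, mass 1), the table
#: conventionally paired with the two scales above in pseudo amino acid
#: composition work.
SIDE_CHAIN_MASS: dict[str, float] = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0,
    "G": 1.0, "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0,
    "M": 75.0, "N": 58.0, "P": 42.0, "Q": 72.0, "R": 101.0,
    "S": 31.0, "T": 45.0, "V": 43.0, "W": 130.0, "Y": 107.0,
}

#: Average (isotope-abundance weighted) residue masses in Daltons, i.e. the
#: amino-acid mass minus one water; summing these and adding WATER_MASS gives
#: the average molecular weight of the peptide.
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "A": 71.08, "C": 103.14, "D": 115.09, "E": 129.12, "F": 147.18,
    "G": 57.05, "H": 137.14, "I": 113.16, "K": 128.17, "L": 113.16,
    "M": 131.19, "N": 114.10, "P": 97.12, "Q": 128.13, "R": 156.19,
    "S": 87.08, "T": 101.10, "V": 99.13, "W": 186.21, "Y": 163.18,
}

#: Average mass of water, added once per chain for the termini.
WATER_MASS: float = 18.02

#: EMBOSS-style pKa values for the ionizable groups. Keys "Nterm"/"Cterm"
#: are the backbone termini; single letters are side chains.
EMBOSS_PKA: dict[str, float] = {
    "Nterm": 8.6, "Cterm": 3.6,
    "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5,
    "K": 10.8, "R": 12.5, "Y": 10.1,
}

#: Side chains that are positively charged when protonated.
BASIC_RESIDUES: tuple[str, ...] = ("K", "R", "H")
#: Side chains that are negatively charged when deprotonated.
ACIDIC_RESIDUES: tuple[str, ...] = ("C", "D", "E", "Y")
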