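"""Packaged lookup tables: hydrophobicity, masses, radii, ASP constants."""

from __future__ import annotations

#: Eisenberg consensus hydrophobicity scale (normalized, dimensionless).
EISENBERG = {
    "A": 0.25, "R": -1.80, "N": -0.64, "D": -0.72, "C": 0.04,
    "Q": -0.69, "E": -0.62, "G": 0.16, "H": -0.40, "I": 0.73,
    "L": 0.53, "K": -1.10, "M": 0.26, "F": 0.61, "P": -0.07,
    "S": -0.26, "T": -0.18, "W": 0.37, "Y": 0.02, "V": 0.54,
}

#: Average (isotope-abundance weighted) residue masses, Da.
RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

#: Mass of one water molecule, Da (added once per chain on condensation).
WATER_MASS = 18.02

#: van der Waals radii by element, Angstrom.
VDW_RADIUS = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

#: Residue character classes used for reduced atom typing and scoring.
HYDROPHOBIC = frozenset("AVLIMFWC")
POSITIVE = frozenset("KR")
NEGATIVE = frozenset("DE")

#: Atomic solvation parameters (octanol/water-transfer style, per atom
#: class, arbitrary units per A^2).  Apolar carbon is favorable to
#: desolvate (negative); polar/charged nitrogen and oxygen unfavorable.
#: A simplified re-parameterization with the standard ranking semantics,
#: not the published optimal-docking-area constants.
ASP = {
    "C_apolar": -0.017,
    "C_polar": -0.003,
    "N": 0.010,
    "O": 0.012,
    "charged": 0.035,
}


def residue_class(res: str) -> str:
    """hydrophobic / positive / negative / polar class of a residue."""
    if res in HYDROPHOBIC:
        return "hydrophobic"
    if res in POSITIVE:
        return "positive"
    if res in NEGATIVE:
        return "negative"
    return "polar"


def atom_asp_class(atom_name: str, element: str, residue_type: str) -> str:
    """ASP class of one atom for desolvation-patch scoring."""
    if atom_name == "CB" and residue_type in (POSITIVE | NEGATIVE):
        return "charged"
    if element == "N":
        return "N"
    if element == "O":
        return "O"
    if atom_name == "CA" or atom_name == "C":
        return "C_polar"  # backbone carbons adjacent to polar groups
    return "C_apolar"
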