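"""Reference data: histone sequences, tail boundaries, atom sets, charges.

The bundled histone sequences are the canonical vertebrate core histones
(the histone complement of the Xenopus laevis reconstituted nucleosome).
They are used for sequence-identity typing of protein chains, which needs
only ~40% ungapped identity, and for building reference-sequence synthetic
octamers; they are reference-grade for those purposes and configurable for
variant histones (CENP-A, H2A.Z, ...).
"""

from __future__ import annotations

# --- canonical core histone sequences (one-letter) -------------------------

HISTONE_SEQUENCES: dict[str, str] = {
    "H3": (
        "ARTKQTARKSTGGKAPRKQLATKAARKSAPATGGVKKPHRYRPGTVALREIRRYQKSTELLIRKLPFQRL"
        "VREIAQDFKTDLRFQSSAVMALQEACEAYLVGLFEDTNLCAIHAKRVTIMPKDIQLARRIRGERA"
    ),
    "H4": (
        "SGRGKGGKGLGKGGAKRHRKVLRDNIQGITKPAIRRLARRGGVKRISGLIYEETRGVLKVFLENVIRDAV"
        "TYTEHAKRKTVTAMDVVYALKRQGRTLYGFGG"
    ),
    "H2A": (
        "SGRGKQGGKARAKAKTRSSRAGLQFPVGRVHRLLRKGNYAERVGAGAPVYLAAVLEYLTAEILELAGNAA"
        "RDNKKTRIIPRHLQLAVRNDEELNKLLGGVTIAQGGVLPNIQSVLLPKKTESSKSAKSK"
    ),
    "H2B": (
        "PEPAKSAPAPKKGSKKAVTKTQKKDGKKRKRSRKESYAIYVYKVLKQVHPDTGISSKAMSIMNSFVNDVF"
        "ERIAGEASRLAHYNKRSTITSREIQTAVRLLLPGELAKHAVSEGTKAVTKYTSAK"
    ),
}

HISTONE_TYPES = ("H3", "H4", "H2A", "H2B")

# --- tail / globular domain boundaries -------------------------------------

# residue ranges (inclusive, file numbering starting at 1) counted as tail;
# everything else is the structured (globular) domain.  H2A additionally has
# a flexible C-terminus.
DEFAULT_TAIL_RANGES: dict[str, list[tuple[int, int]]] = {
    "H3": [(1, 36)],
    "H4": [(1, 24)],
    "H2A": [(1, 13), (119, 129)],
    "H2B": [(1, 30)],
}

# --- residue chemistry ------------------------------------------------------

AA3TO1: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "MSE": "M", "SEC": "C", "PYL": "K",
}

# unit charges of the coarse-grained convention: only Lys/Arg/Glu/Asp carry
# charge; His is neutral.
RESIDUE_CHARGES: dict[str, int] = {"LYS": +1, "ARG": +1, "GLU": -1, "ASP": -1}

# nucleic residue names mapped to their parent base
NUCLEOTIDE_PARENT: dict[str, str] = {
    "DA": "DA", "DT": "DT", "DG": "DG", "DC": "DC", "DU": "DU",
    "A": "DA", "T": "DT", "G": "DG", "C": "DC", "U": "DU",
    "ADE": "DA", "THY": "DT", "GUA": "DG", "CYT": "DC", "URA": "DU",
    "5CM": "DC", "5MC": "DC", "BRU": "DT", "5IU": "DT", "6MA": "DA",
    "8OG": "DG", "DI": "DG",
}

_PURINE_RING = ["N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"]
_PYRIMIDINE_RING = ["N1", "C2", "O2", "N3", "C4", "C5", "C6"]

# heavy atoms of the base moiety, per parent base, used for bp centroids
BASE_HEAVY_ATOMS: dict[str, list[str]] = {
    "DA": _PURINE_RING + ["N6"],
    "DG": _PURINE_RING + ["O6", "N2"],
    "DT": _PYRIMIDINE_RING + ["O4", "C7", "C5M"],
    "DC": _PYRIMIDINE_RING + ["N4"],
    "DU": _PYRIMIDINE_RING + ["O4"],
}

# --- ionic-contact atom convention ------------------------------------------

BASIC_ATOMS: dict[str, str] = {"LYS": "NZ", "ARG": "CZ"}
ACIDIC_ATOMS: dict[str, str] = {"GLU": "CD", "ASP": "CG"}
DNA_PHOSPHORUS = "P"

# --- acidic patch -----------------------------------------------------------

# (histone type, residue name, residue number) per copy, canonical numbering
ACIDIC_PATCH: list[tuple[str, str, int]] = [
    ("H2A", "GLU", 56),
    ("H2A", "GLU", 61),
    ("H2A", "GLU", 64),
    ("H2A", "ASP", 90),
    ("H2A", "GLU", 91),
    ("H2A", "GLU", 92),
    ("H2B", "GLU", 110),
]

# --- element masses (Da) for mass-weighted centres --------------------------

ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "SE": 78.971, "FE": 55.845, "ZN": 65.38, "MG": 24.305,
    "MN": 54.938, "NA": 22.990, "K": 39.098, "CL": 35.45, "BR": 79.904,
    "I": 126.904, "CO": 58.933,
}


def element_mass(element: str) -> float:
    return ELEMENT_MASSES.get(element.upper().strip(), 12.011)


def one_letter_sequence(resnames: list[str]) -> str:
    return "".join(AA3TO1.get(r.upper(), "X") for r in resnames)


def is_amino(resname: str) -> bool:
    return resname.upper() in AA3TO1


def is_nucleic(resname: str) -> bool:
    return resname.upper() in NUCLEOTIDE_PARENT
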