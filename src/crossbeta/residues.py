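"""Amino-acid bookkeeping shared across modules.

The four-class residue typing (hydrophobic / polar / charged / other) is the
hydration-property vocabulary used throughout the design stage: composition
constraints are expressed as per-class counts and mutation moves must stay
within a class.
"""

from __future__ import annotations

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

HYDROPHOBIC = frozenset("LVIAMFYWG")
POLAR = frozenset("STHNQ")
CHARGED = frozenset("RKDE")
OTHER = frozenset("CP")

RESIDUE_CLASSES: dict[str, str] = {}
for _aa in AMINO_ACIDS:
    if _aa in HYDROPHOBIC:
        RESIDUE_CLASSES[_aa] = "hydrophobic"
    elif _aa in POLAR:
        RESIDUE_CLASSES[_aa] = "polar"
    elif _aa in CHARGED:
        RESIDUE_CLASSES[_aa] = "charged"
    else:
        RESIDUE_CLASSES[_aa] = "other"

CLASS_MEMBERS: dict[str, str] = {
    "hydrophobic": "".join(sorted(HYDROPHOBIC)),
    "polar": "".join(sorted(POLAR)),
    "charged": "".join(sorted(CHARGED)),
    "other": "".join(sorted(OTHER)),
}

#: formal side-chain charge at neutral pH (His treated as neutral/polar)
SIDE_CHAIN_CHARGE: dict[str, int] = {aa: 0 for aa in AMINO_ACIDS}
SIDE_CHAIN_CHARGE.update({"R": +1, "K": +1, "D": -1, "E": -1})

THREE_LETTER: dict[str, str] = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
ONE_LETTER: dict[str, str] = {v: k for k, v in THREE_LETTER.items()}


def check_sequence(sequence: str) -> str:
    """Validate a one-letter sequence, returning it unchanged."""
    for ch in sequence:
        if ch not in RESIDUE_CLASSES:
            raise ValueError(f"unknown amino-acid code {ch!r}")
    return sequence
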