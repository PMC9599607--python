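"""Covalent topology templates for the 20 standard amino acids.

Heavy-atom connectivity only; hydrogens are attached geometrically
(nearest heavy atom in the same residue) because PDB hydrogen naming is
too variable to template reliably.
"""

from __future__ import annotations

# Backbone bonds shared by every standard residue (CA-CB added per residue).
BACKBONE_BONDS: tuple[tuple[str, str], ...] = (("N", "CA"), ("CA", "C"), ("C", "O"))

# Side-chain heavy-atom bonds, including CA-CB where a CB exists.
SIDECHAIN_BONDS: dict[str, tuple[tuple[str, str], ...]] = {
    "ALA": (("CA", "CB"),),
    "ARG": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "NE"), ("NE", "CZ"),
            ("CZ", "NH1"), ("CZ", "NH2")),
    "ASN": (("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")),
    "ASP": (("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")),
    "CYS": (("CA", "CB"), ("CB", "SG")),
    "GLN": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "NE2")),
    "GLU": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "OE2")),
    "GLY": (),
    "HIS": (("CA", "CB"), ("CB", "CG"), ("CG", "ND1"), ("ND1", "CE1"), ("CE1", "NE2"),
            ("NE2", "CD2"), ("CD2", "CG")),
    "ILE": (("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")),
    "LEU": (("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")),
    "LYS": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"), ("CE", "NZ")),
    "MET": (("CA", "CB"), ("CB", "CG"), ("CG", "SD"), ("SD", "CE")),
    "PHE": (("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CD1", "CE1"), ("CE1", "CZ"),
            ("CZ", "CE2"), ("CE2", "CD2"), ("CD2", "CG")),
    "PRO": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")),
    "SER": (("CA", "CB"), ("CB", "OG")),
    "THR": (("CA", "CB"), ("CB", "OG1"), ("CB", "CG2")),
    "TRP": (("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CD1", "NE1"), ("NE1", "CE2"),
            ("CE2", "CD2"), ("CD2", "CG"), ("CE2", "CZ2"), ("CZ2", "CH2"),
            ("CH2", "CZ3"), ("CZ3", "CE3"), ("CE3", "CD2")),
    "TYR": (("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CD1", "CE1"), ("CE1", "CZ"),
            ("CZ", "CE2"), ("CE2", "CD2"), ("CD2", "CG"), ("CZ", "OH")),
    "VAL": (("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")),
}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

STANDARD_RESIDUES = frozenset(THREE_TO_ONE)

# Atoms belonging to planar ring systems (their internal bonds are locked).
RING_ATOMS: dict[str, frozenset[str]] = {
    "HIS": frozenset({"CG", "ND1", "CE1", "NE2", "CD2"}),
    "PHE": frozenset({"CG", "CD1", "CE1", "CZ", "CE2", "CD2"}),
    "TYR": frozenset({"CG", "CD1", "CE1", "CZ", "CE2", "CD2"}),
    "TRP": frozenset({"CG", "CD1", "NE1", "CE2", "CD2", "CZ2", "CH2", "CZ3", "CE3"}),
    "PRO": frozenset({"N", "CA", "CB", "CG", "CD"}),
}


def residue_bonds(resname: str) -> tuple[tuple[str, str], ...]:
    """All heavy-atom bonds of a standard residue, or () if unknown."""
    if resname not in SIDECHAIN_BONDS:
        return ()
    return BACKBONE_BONDS + SIDECHAIN_BONDS[resname]
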