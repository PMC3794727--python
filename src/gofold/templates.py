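"""Heavy-atom covalent connectivity templates for the standard amino acids.

Each entry lists the intra-residue bonds among heavy atoms with standard PDB
names.  The backbone bonds N-CA, CA-C, C-O (and C-OXT when a terminal oxygen is
present) are common to all residues; inter-residue peptide bonds C(i)-N(i+1)
are added by the bond-network builder.
"""

from __future__ import annotations

BACKBONE_BONDS: list[tuple[str, str]] = [("N", "CA"), ("CA", "C"), ("C", "O")]

SIDECHAIN_BONDS: dict[str, list[tuple[str, str]]] = {
    "GLY": [],
    "ALA": [("CA", "CB")],
    "SER": [("CA", "CB"), ("CB", "OG")],
    "CYS": [("CA", "CB"), ("CB", "SG")],
    "THR": [("CA", "CB"), ("CB", "OG1"), ("CB", "CG2")],
    "VAL": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")],
    "LEU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
    "ILE": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")],
    "MET": [("CA", "CB"), ("CB", "CG"), ("CG", "SD"), ("SD", "CE")],
    "PRO": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")],
    "PHE": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")],
    "TYR": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"),
            ("CZ", "OH")],
    "TRP": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "NE1"), ("NE1", "CE2"), ("CD2", "CE2"), ("CD2", "CE3"),
            ("CE3", "CZ3"), ("CZ3", "CH2"), ("CH2", "CZ2"), ("CZ2", "CE2")],
    "ASP": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
    "GLU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "OE2")],
    "ASN": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")],
    "GLN": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "NE2")],
    "LYS": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"),
            ("CE", "NZ")],
    "ARG": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "NE"),
            ("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2")],
    "HIS": [("CA", "CB"), ("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"),
            ("ND1", "CE1"), ("CD2", "NE2"), ("CE1", "NE2")],
}

# Synthetic backbone-only residue used by the minifold generator: a glycine
# without the carbonyl oxygen is not standard PDB content, so the generator
# emits full GLY residues and needs no extra template.


def residue_bonds(residue_name: str, atom_names: set[str]) -> list[tuple[str, str]]:
    """Intra-residue bond list for ``residue_name`` restricted to present atoms.

    Unknown residue names fall back to backbone-only connectivity.
    """
    bonds = list(BACKBONE_BONDS) + SIDECHAIN_BONDS.get(residue_name.upper(), [])
    if "OXT" in atom_names:
        bonds.append(("C", "OXT"))
    return [(a, b) for a, b in bonds if a in atom_names and b in atom_names]
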