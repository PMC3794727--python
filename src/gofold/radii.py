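"""Heavy-atom van der Waals radii and their assignment to parsed atoms.

Atoms are binned into a small number of classes (aliphatic carbon, sp2/carbonyl
carbon, aromatic carbon, N, O, S, P).  Hard-core distances in the model are
``sigma_ij = alpha * (r_i + r_j)`` and the attraction range is ``lambda * sigma``,
so for a pair of methyl carbons the default table gives a cutoff of
``1.6 * 0.80 * 2 * 1.836 = 4.70 Å``.
"""

from __future__ import annotations

import csv
from importlib import resources

__all__ = ["load_radii_table", "classify_atom", "assign_radii", "UnassignedRadiusError"]


class UnassignedRadiusError(KeyError):
    """Raised when an atom maps to a class missing from the radii table."""


def load_radii_table() -> dict[str, float]:
    """Return the packaged ``class -> radius (Å)`` table."""
    table: dict[str, float] = {}
    path = resources.files("gofold.data").joinpath("vdw_radii.tsv")
    with path.open() as fh:
        for row in csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        ):
            table[row["class"]] = float(row["radius"])
    return table


# sp2 (trigonal) carbons by residue: carbonyl/carboxyl/amide/guanidinium.
_SP2_CARBONS = {
    ("ASP", "CG"), ("GLU", "CD"), ("ASN", "CG"), ("GLN", "CD"), ("ARG", "CZ"),
}
# aromatic ring carbons
_ARO_CARBONS = {
    ("PHE", n) for n in ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
} | {
    ("TYR", n) for n in ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
} | {
    ("TRP", n) for n in ("CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")
} | {
    ("HIS", n) for n in ("CG", "CD2", "CE1")
}


def classify_atom(residue_name: str, atom_name: str, element: str) -> str:
    """Map an atom to its radii-table class.

    Backbone carbonyl carbon ("C") is sp2; ring carbons of aromatic residues are
    aromatic; every other carbon (CA, CB, side-chain methyl(ene)s) is aliphatic.
    Non-carbon elements map directly to their element symbol.
    """
    el = element.upper()
    if el != "C":
        return el
    name = atom_name.upper()
    res = residue_name.upper()
    if name == "C":
        return "C_SP2"
    if (res, name) in _SP2_CARBONS:
        return "C_SP2"
    if (res, name) in _ARO_CARBONS:
        return "C_ARO"
    return "C_ALI"


def assign_radii(atoms, radii_table: dict[str, float] | None = None):
    """Attach a vdW radius to every atom; returns the same list.

    Raises
    ------
    UnassignedRadiusError
        If an atom's class has no entry in the table.
    """
    table = load_radii_table() if radii_table is None else radii_table
    for atom in atoms:
        cls = classify_atom(atom.residue_name, atom.name, atom.element)
        if cls not in table:
            raise UnassignedRadiusError(
                f"unassigned radius: class {cls!r} for atom {atom.name} "
                f"in {atom.residue_name} {atom.residue_index}"
            )
        radius = table[cls]
        if radius <= 0:
            raise ValueError(f"non-positive radius for class {cls!r}")
        atom.vdw_radius = radius
    return atoms
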