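"""Native-structure model: PDB parsing, bonded topology and the Gō contact set.

The model represents every heavy atom as a hard sphere of unit mass.  Covalent
and covalent-like (angle/planarity-preserving) bonds are narrow infinite wells
around the native pair distance; every atom pair in residues more than two
sequence positions apart whose native separation lies inside the attractive
range ``[sigma_ij, lambda*sigma_ij)`` is a native contact of depth -1
(``sigma_ij = alpha*(r_i + r_j)``).  Disulfides are deliberately treated as
ordinary contacts, never as bonds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

from .radii import assign_radii  # re-exported for convenience
from .templates import residue_bonds

__all__ = [
    "AtomRecord",
    "BondNetwork",
    "NativeContactSet",
    "SegmentMap",
    "BETA2M_SEGMENTS",
    "StructureModel",
    "load_structure",
    "assign_radii",
    "write_pdb",
    "build_bond_network",
    "build_native_contacts",
    "segment_contact_counts",
    "write_contacts_tsv",
    "NativeClashError",
]

PEPTIDE_BOND_MAX = 2.0  # Å; C(i)-N(i+1) beyond this is a chain break
BOND_WELL_LO = 0.9
BOND_WELL_HI = 1.1


class NativeClashError(ValueError):
    """A putative native pair sits inside its own hard core."""


@dataclass
class AtomRecord:
    index: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain: str
    position: np.ndarray  # (3,) Å
    vdw_radius: float = 0.0
    mass: float = 1.0


@dataclass
class BondNetwork:
    """Covalent bonds and covalent-like pseudo-bonds with ±10% wells."""

    covalent_bonds: list[tuple[int, int, float]]
    pseudo_bonds: list[tuple[int, int, float]]
    warnings: list[str] = field(default_factory=list)

    def all_bonds(self) -> list[tuple[int, int, float]]:
        return self.covalent_bonds + self.pseudo_bonds

    def well(self, length: float) -> tuple[float, float]:
        return BOND_WELL_LO * length, BOND_WELL_HI * length

    def bonded_pairs(self) -> set[tuple[int, int]]:
        return {(min(i, j), max(i, j)) for i, j, _ in self.all_bonds()}


@dataclass
class NativeContactSet:
    """Atom-level native contacts: (i, j, sigma_ij) with i < j, depth -1."""

    pairs: list[tuple[int, int]]
    sigma: np.ndarray        # hard-core distance per pair, Å
    alpha: float
    lam: float

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def attraction_edge(self) -> np.ndarray:
        return self.lam * self.sigma

    def residue_pair_counts(self, atoms: list[AtomRecord]) -> dict[tuple[int, int], int]:
        counts: dict[tuple[int, int], int] = {}
        for i, j in self.pairs:
            ri, rj = atoms[i].residue_index, atoms[j].residue_index
            key = (min(ri, rj), max(ri, rj))
            counts[key] = counts.get(key, 0) + 1
        return counts


@dataclass
class SegmentMap:
    """Named residue ranges (inclusive), e.g. the β-strands and loops of β2m."""

    segments: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        items = sorted(self.segments.items(), key=lambda kv: kv[1])
        for (la, (a0, a1)), (lb, (b0, b1)) in zip(items, items[1:]):
            if b0 <= a1:
                raise ValueError(f"segments {la!r} and {lb!r} overlap")
        for label, (lo, hi) in self.segments.items():
            if lo > hi:
                raise ValueError(f"segment {label!r} has inverted range")

    def residues(self, label: str) -> range:
        lo, hi = self.segments[label]
        return range(lo, hi + 1)


#: β2m strand/loop decomposition (PDB residue numbering of the mature chain).
BETA2M_SEGMENTS = SegmentMap({
    "A": (6, 12), "AB": (13, 21), "B": (22, 30), "BC": (31, 35),
    "C": (36, 41), "C'": (44, 45), "D": (51, 56), "DE": (57, 61),
    "E": (62, 69), "EF": (70, 77), "F": (78, 83), "FG": (84, 90),
    "G": (91, 94),
})


def load_structure(pdb_text: str, chain: str | None = None) -> list[AtomRecord]:
    """Parse ATOM records of one chain into :class:`AtomRecord` s.

    Hydrogens (and deuteriums) are dropped, only the first MODEL is read, and
    for alternate locations the highest-occupancy conformer is kept.  Residues
    keep their PDB sequence numbers.
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise ValueError("empty structure: no ATOM records")
    model = st[0]
    chains = [ch for ch in model if chain is None or ch.name == chain]
    atoms: list[AtomRecord] = []
    for ch in chains:
        for res in ch:
            if res.het_flag != "A":  # HETATM / solvent
                continue
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for at in res:
                el = at.element.name or _infer_element(at.name)
                if el.upper() in ("H", "D"):
                    continue
                if at.name not in best:
                    order.append(at.name)
                    best[at.name] = at
                elif at.occ > best[at.name].occ:
                    best[at.name] = at
            for name in order:
                at = best[name]
                el = at.element.name or _infer_element(at.name)
                if not el:
                    raise ValueError(f"unresolvable element for atom {at.name!r}")
                pos = np.array([at.pos.x, at.pos.y, at.pos.z], dtype=float)
                if not np.all(np.isfinite(pos)):
                    raise ValueError(f"non-finite coordinates for atom {at.name!r}")
                atoms.append(AtomRecord(
                    index=len(atoms), name=at.name, element=el,
                    residue_index=res.seqid.num, residue_name=res.name,
                    chain=ch.name, position=pos,
                ))
        if atoms:
            break  # one chain per model
    if not atoms:
        raise ValueError("empty structure: no ATOM records for requested chain")
    return atoms


def _infer_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else ""


def build_bond_network(atoms: list[AtomRecord], alpha: float = 0.80) -> BondNetwork:
    """Covalent bonds from residue templates plus covalent-like pseudo-bonds.

    Pseudo-bonds constrain (a) all second covalent neighbours (1-3 pairs), which
    fixes bond angles, (b) the CA(i)-CA(i+1) distance across each peptide bond,
    which fixes the peptide-plane geometry, and (c) any remaining short-range
    pair (residue separation <= 2) whose native distance would violate the hard
    core — local native geometry that the square-well core cannot accommodate
    is held by a covalent-like constraint instead.
    All wells are [0.9 L, 1.1 L] with L the native pair distance.
    """
    pos = np.array([a.position for a in atoms])
    by_key = {(a.residue_index, a.name): a.index for a in atoms}
    residues: list[tuple[int, str]] = []
    for a in atoms:
        if not residues or residues[-1][0] != a.residue_index:
            residues.append((a.residue_index, a.residue_name))

    def dist(i: int, j: int) -> float:
        return float(np.linalg.norm(pos[i] - pos[j]))

    covalent: list[tuple[int, int, float]] = []
    warnings: list[str] = []
    names_by_res: dict[int, set[str]] = {}
    for a in atoms:
        names_by_res.setdefault(a.residue_index, set()).add(a.name)

    for rid, rname in residues:
        for na, nb in residue_bonds(rname, names_by_res[rid]):
            i, j = by_key[(rid, na)], by_key[(rid, nb)]
            covalent.append((i, j, dist(i, j)))
    for (rid_a, _), (rid_b, _) in zip(residues, residues[1:]):
        ci, nj = by_key.get((rid_a, "C")), by_key.get((rid_b, "N"))
        if ci is None or nj is None:
            warnings.append(f"chain discontinuity: missing C/N between {rid_a} and {rid_b}")
            continue
        d = dist(ci, nj)
        if rid_b != rid_a + 1 or d > PEPTIDE_BOND_MAX:
            warnings.append(f"chain discontinuity between residues {rid_a} and {rid_b}")
            continue
        covalent.append((ci, nj, d))

    # 1-3 pseudo-bonds from the covalent graph
    neighbors: dict[int, set[int]] = {}
    for i, j, _ in covalent:
        neighbors.setdefault(i, set()).add(j)
        neighbors.setdefault(j, set()).add(i)
    cov_pairs = {(min(i, j), max(i, j)) for i, j, _ in covalent}
    pseudo_pairs: set[tuple[int, int]] = set()
    for mid, nbrs in neighbors.items():
        for i in nbrs:
            for j in nbrs:
                if i < j and (i, j) not in cov_pairs:
                    pseudo_pairs.add((i, j))
    # peptide-plane constraint: CA(i)-CA(i+1)
    for (rid_a, _), (rid_b, _) in zip(residues, residues[1:]):
        ca_i, ca_j = by_key.get((rid_a, "CA")), by_key.get((rid_b, "CA"))
        ci = by_key.get((rid_a, "C"))
        if ca_i is None or ca_j is None or ci is None:
            continue
        if (min(ci, by_key[(rid_b, "N")]), max(ci, by_key[(rid_b, "N")])) not in cov_pairs:
            continue  # chain break: no plane to preserve
        pseudo_pairs.add((min(ca_i, ca_j), max(ca_i, ca_j)))

    # core-violating short-range pairs become covalent-like constraints
    if all(a.vdw_radius > 0 for a in atoms):
        rad = np.array([a.vdw_radius for a in atoms])
        res_idx = np.array([a.residue_index for a in atoms])
        n = len(atoms)
        d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
        sig = alpha * (rad[:, None] + rad[None, :])
        sep = np.abs(res_idx[:, None] - res_idx[None, :])
        ii, jj = np.triu_indices(n, k=1)
        close = d2[ii, jj] < sig[ii, jj] ** 2
        short = sep[ii, jj] <= 2
        for i, j in zip(ii[close & short], jj[close & short]):
            p = (int(i), int(j))
            if p not in cov_pairs:
                pseudo_pairs.add(p)

    pseudo = [(i, j, dist(i, j)) for i, j in sorted(pseudo_pairs)]
    return BondNetwork(covalent_bonds=covalent, pseudo_bonds=pseudo, warnings=warnings)


def build_native_contacts(
    atoms: list[AtomRecord], alpha: float = 0.80, lam: float = 1.6
) -> NativeContactSet:
    """Atom pairs with residue separation > 2 inside their attractive well.

    A pair is a native contact iff ``|res_i - res_j| > 2`` and the native
    distance satisfies ``sigma_ij <= r_ij < lambda*sigma_ij``.  A native
    distance below the hard core raises :class:`NativeClashError`.
    """
    if not all(a.vdw_radius > 0 for a in atoms):
        raise ValueError("radii must be assigned before building contacts")
    pos = np.array([a.position for a in atoms])
    rad = np.array([a.vdw_radius for a in atoms])
    res_idx = np.array([a.residue_index for a in atoms])
    n = len(atoms)
    ii, jj = np.triu_indices(n, k=1)
    sep = np.abs(res_idx[ii] - res_idx[jj])
    eligible = sep > 2
    ii, jj = ii[eligible], jj[eligible]
    d = np.linalg.norm(pos[ii] - pos[jj], axis=1)
    sig = alpha * (rad[ii] + rad[jj])
    clashing = d < sig
    if np.any(clashing):
        offenders = [(int(a), int(b)) for a, b in zip(ii[clashing], jj[clashing])]
        raise NativeClashError(f"native hard-core clash for pairs {offenders[:20]}")
    within = d < lam * sig
    pairs = [(int(a), int(b)) for a, b in zip(ii[within], jj[within])]
    return NativeContactSet(pairs=pairs, sigma=sig[within].copy(), alpha=alpha, lam=lam)


def segment_contact_counts(
    contacts: NativeContactSet,
    atoms: list[AtomRecord],
    segments: SegmentMap,
    reference: dict[str, int] | None = None,
) -> dict[str, dict]:
    """Per-segment native-contact counts (Table-style aggregation).

    A contact is credited to a segment when at least one partner atom's residue
    lies in the segment; a contact with both partners in the same segment is
    counted once.  If ``reference`` maps labels to counts of another variant,
    the percent change is reported alongside.
    """
    chain_residues = {a.residue_index for a in atoms}
    out: dict[str, dict] = {}
    for label, (lo, hi) in segments.segments.items():
        members = set(range(lo, hi + 1))
        empty = not (members & chain_residues)
        count = 0
        for i, j in contacts.pairs:
            ri, rj = atoms[i].residue_index, atoms[j].residue_index
            if ri in members or rj in members:
                count += 1
        entry: dict = {"count": count, "empty_segment": empty}
        if reference is not None and label in reference and reference[label] > 0:
            entry["pct_change"] = 100.0 * (count - reference[label]) / reference[label]
        out[label] = entry
    return out


@dataclass
class StructureModel:
    """Parsed atoms with radii, bonded topology and the native contact set."""

    atoms: list[AtomRecord]
    bonds: BondNetwork
    contacts: NativeContactSet
    alpha: float = 0.80
    lam: float = 1.6

    @classmethod
    def from_pdb(
        cls,
        pdb_text: str,
        chain: str | None = None,
        alpha: float = 0.80,
        lam: float = 1.6,
        radii_table: dict[str, float] | None = None,
    ) -> "StructureModel":
        atoms = assign_radii(load_structure(pdb_text, chain), radii_table)
        bonds = build_bond_network(atoms, alpha=alpha)
        contacts = build_native_contacts(atoms, alpha=alpha, lam=lam)
        return cls(atoms=atoms, bonds=bonds, contacts=contacts, alpha=alpha, lam=lam)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    @property
    def native_energy(self) -> float:
        return -float(len(self.contacts))

    def ca_indices(self) -> np.ndarray:
        return np.array([a.index for a in self.atoms if a.name == "CA"], dtype=int)


def write_pdb(atoms: list[AtomRecord], positions: np.ndarray | None = None) -> str:
    """Minimal single-model PDB text (ATOM records + TER/END)."""
    lines = []
    pos = np.array([a.position for a in atoms]) if positions is None else np.asarray(positions)
    for a, p in zip(atoms, pos):
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        lines.append(
            f"ATOM  {a.index + 1:5d} {name}{'':1s}{a.residue_name:>3s} "
            f"{a.chain:1s}{a.residue_index:4d}    "
            f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {a.element:>2s}"
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_contacts_tsv(contacts: NativeContactSet, path: str) -> None:
    """Sparse triplet file: atom i, atom j, hard-core distance sigma_ij."""
    with open(path, "w") as fh:
        fh.write("i\tj\tsigma\n")
        for (i, j), s in zip(contacts.pairs, contacts.sigma):
            fh.write(f"{i}\t{j}\t{s:.6f}\n")
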