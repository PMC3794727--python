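"""Structure model: parsing, radii, bonded topology, native contacts."""

import numpy as np
import pytest

from gofold.radii import UnassignedRadiusError, assign_radii, classify_atom, load_radii_table
from gofold.structure import (
    NativeClashError,
    SegmentMap,
    build_bond_network,
    build_native_contacts,
    load_structure,
    segment_contact_counts,
    write_pdb,
)
from gofold.templates import residue_bonds

ALPHA, LAM = 0.80, 1.6


def brute_force_contacts(atoms, alpha=ALPHA, lam=LAM):
    """Independent O(N^2) scan with explicit loops."""
    pairs = []
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            a, b = atoms[i], atoms[j]
            if abs(a.residue_index - b.residue_index) <= 2:
                continue
            d = float(np.linalg.norm(a.position - b.position))
            if d < lam * alpha * (a.vdw_radius + b.vdw_radius):
                pairs.append((i, j))
    return pairs


class TestLoadStructure:
    def test_minifold_roundtrip(self, minifold):
        atoms = load_structure(minifold.pdb_text, chain="A")
        orig = minifold.model.atoms
        assert len(atoms) == len(orig)
        for a, b in zip(atoms, orig):
            assert a.name == b.name and a.residue_index == b.residue_index
            # PDB format stores 3 decimals
            assert np.allclose(a.position, b.position, atol=5e-4)

    def test_no_atom_records_raises(self):
        with pytest.raises(ValueError, match="empty structure"):
            load_structure(
                "HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\n"
                "END\n"
            )

    def test_hydrogens_dropped_and_altloc_resolved(self):
        text = (
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  H   ALA A   1       1.000   0.000   0.000  1.00  0.00           H\n"
            "ATOM      3  CA AALA A   1       1.458   0.000   0.000  0.30  0.00           C\n"
            "ATOM      4  CA BALA A   1       2.458   0.000   0.000  0.70  0.00           C\n"
            "END\n"
        )
        atoms = load_structure(text, chain="A")
        assert [a.name for a in atoms] == ["N", "CA"]
        assert atoms[1].position[0] == pytest.approx(2.458)  # higher occupancy wins


class TestRadii:
    def test_methyl_carbon_cutoff_is_4p7(self):
        table = load_radii_table()
        r = table["C_ALI"]
        assert LAM * ALPHA * 2 * r == pytest.approx(4.7, abs=5e-3)

    def test_missing_sulfur_entry_raises(self, minifold):
        text = (
            "ATOM      1  CB  CYS A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  SG  CYS A   1       1.800   0.000   0.000  1.00  0.00           S\n"
            "END\n"
        )
        atoms = load_structure(text, chain="A")
        table = {k: v for k, v in load_radii_table().items() if k != "S"}
        with pytest.raises(UnassignedRadiusError, match="unassigned radius"):
            assign_radii(atoms, table)

    def test_all_radii_positive(self, minifold):
        assert all(a.vdw_radius > 0 for a in minifold.model.atoms)

    def test_carbon_classes(self):
        assert classify_atom("ALA", "CB", "C") == "C_ALI"
        assert classify_atom("ALA", "C", "C") == "C_SP2"
        assert classify_atom("PHE", "CZ", "C") == "C_ARO"
        assert classify_atom("CYS", "SG", "S") == "S"


class TestBondNetwork:
    def test_three_atom_toy_chain(self):
        # one glycine-like residue with N-CA-C gives 2 covalent bonds and
        # the 1-3 pseudo-bond N..C
        text = (
            "ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  CA  GLY A   1       1.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      3  C   GLY A   1       2.000   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        atoms = load_structure(text, chain="A")
        net = build_bond_network(atoms)
        assert len(net.covalent_bonds) == 2
        assert len(net.pseudo_bonds) == 1
        (i, j, length) = net.pseudo_bonds[0]
        assert (i, j) == (0, 2) and length == pytest.approx(2.0)
        lo, hi = net.well(1.0)
        assert (lo, hi) == (0.9, 1.1)

    def test_bond_count_matches_template_walk(self, minifold):
        """Covalent bond count from an independent brute-force template walk."""
        atoms = minifold.model.atoms
        by_res: dict[int, set] = {}
        for a in atoms:
            by_res.setdefault(a.residue_index, set()).add(a.name)
        expected = sum(len(residue_bonds("GLY", names)) for names in by_res.values())
        expected += len(by_res) - 1  # peptide bonds
        assert len(minifold.model.bonds.covalent_bonds) == expected

    def test_chain_break_records_warning(self):
        # residues 1 and 3 (gap): no peptide bond, warning recorded
        text = (
            "ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C\n"
            "ATOM      3  C   GLY A   1       2.400   1.000   0.000  1.00  0.00           C\n"
            "ATOM      4  N   GLY A   3      20.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      5  CA  GLY A   3      21.458   0.000   0.000  1.00  0.00           C\n"
            "ATOM      6  C   GLY A   3      22.400   1.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        atoms = load_structure(text, chain="A")
        net = build_bond_network(atoms)
        assert any("discontinuity" in w for w in net.warnings)
        inter = [b for b in net.covalent_bonds if atoms[b[0]].residue_index != atoms[b[1]].residue_index]
        assert inter == []


class TestNativeContacts:
    def test_count_matches_brute_force(self, minifold):
        atoms = minifold.model.atoms
        expected = brute_force_contacts(atoms)
        got = minifold.model.contacts.pairs
        assert sorted(got) == sorted(expected)

    def test_extended_tripeptide_has_no_contacts(self):
        from gofold.synthetic import backbone_from_dihedrals
        from gofold.structure import AtomRecord, StructureModel
        coords = backbone_from_dihedrals([-139.0] * 3, [135.0] * 3)
        names, els = ["N", "CA", "C", "O"], ["N", "C", "C", "O"]
        atoms = [
            AtomRecord(index=4 * i + k, name=names[k], element=els[k],
                       residue_index=i + 1, residue_name="GLY", chain="A",
                       position=coords[4 * i + k])
            for i in range(3) for k in range(4)
        ]
        model = StructureModel.from_pdb(write_pdb(atoms), chain="A")
        assert len(model.contacts) == 0

    def test_native_well_invariant(self, minifold):
        m = minifold.model
        pos = m.positions
        for (i, j), sig in zip(m.contacts.pairs, m.contacts.sigma):
            d = np.linalg.norm(pos[i] - pos[j])
            assert sig <= d < LAM * sig

    def test_clash_raises(self, minifold):
        atoms = [a for a in minifold.model.atoms]
        pos0 = atoms[0].position.copy()
        # move the first atom onto an atom >2 residues away
        atoms[0].position = atoms[-1].position + np.array([0.1, 0.0, 0.0])
        with pytest.raises(NativeClashError, match="hard-core clash"):
            build_native_contacts(atoms)
        atoms[0].position = pos0

    @pytest.mark.parametrize("lam_pair", [(1.3, 1.6), (1.6, 1.9)])
    def test_contact_count_monotone_in_lambda(self, minifold, lam_pair):
        atoms = minifold.model.atoms
        lo = build_native_contacts(atoms, alpha=ALPHA, lam=lam_pair[0])
        hi = build_native_contacts(atoms, alpha=ALPHA, lam=lam_pair[1])
        assert len(hi) >= len(lo)
        assert set(lo.pairs) <= set(hi.pairs)

    def test_contact_count_monotone_in_alpha(self, minifold):
        # the attraction edge is lam*alpha*(r_i + r_j): shrinking alpha can
        # only lose contacts (for alphas that keep the native state clash-free)
        atoms = minifold.model.atoms
        big = build_native_contacts(atoms, alpha=0.80, lam=LAM)
        small = build_native_contacts(atoms, alpha=0.75, lam=LAM)
        assert len(small) <= len(big)
        assert set(small.pairs) <= set(big.pairs)

    def test_residue_relabeling_isomorphic(self, minifold):
        atoms = [a for a in minifold.model.atoms]
        base = build_native_contacts(atoms)
        shift = []
        for a in atoms:
            b = type(a)(index=a.index, name=a.name, element=a.element,
                        residue_index=a.residue_index + 100,
                        residue_name=a.residue_name, chain=a.chain,
                        position=a.position, vdw_radius=a.vdw_radius)
            shift.append(b)
        relabeled = build_native_contacts(shift)
        assert relabeled.pairs == base.pairs


class TestSegments:
    def test_full_chain_segment_equals_total(self, minifold):
        m = minifold.model
        res = [a.residue_index for a in m.atoms]
        seg = SegmentMap({"all": (min(res), max(res))})
        counts = segment_contact_counts(m.contacts, m.atoms, seg)
        assert counts["all"]["count"] == len(m.contacts)

    def test_out_of_range_segment_flagged_zero(self, minifold):
        m = minifold.model
        seg = SegmentMap({"ghost": (200, 210)})
        counts = segment_contact_counts(m.contacts, m.atoms, seg)
        assert counts["ghost"]["count"] == 0
        assert counts["ghost"]["empty_segment"]

    def test_either_partner_crediting(self, minifold):
        """A contact spanning two segments is credited to both."""
        m = minifold.model
        res = sorted({a.residue_index for a in m.atoms})
        mid = res[len(res) // 2]
        seg = SegmentMap({"left": (res[0], mid), "right": (mid + 1, res[-1])})
        counts = segment_contact_counts(m.contacts, m.atoms, seg)
        spanning = sum(
            1 for i, j in m.contacts.pairs
            if (m.atoms[i].residue_index <= mid) != (m.atoms[j].residue_index <= mid)
        )
        assert counts["left"]["count"] + counts["right"]["count"] == \
            len(m.contacts) + spanning

    def test_percent_change_against_reference(self, minifold):
        m = minifold.model
        res = sorted({a.residue_index for a in m.atoms})
        seg = SegmentMap({"all": (res[0], res[-1])})
        ref = {"all": len(m.contacts) * 2}
        counts = segment_contact_counts(m.contacts, m.atoms, seg, reference=ref)
        assert counts["all"]["pct_change"] == pytest.approx(-50.0)

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SegmentMap({"a": (1, 10), "b": (5, 15)})
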