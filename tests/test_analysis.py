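"""Geometric observables, clustering, SASA and populations."""

import math

import numpy as np
import pytest

from gofold.analysis import (
    ConformationEnsemble,
    MacrostateDefinition,
    build_ensemble,
    cluster_kmeans,
    contact_ratio_map,
    macrostate_populations,
    nonpolar_solvation,
    peptide_omega,
    radius_of_gyration,
    sasa_per_atom,
    sasa_ratio_profile,
    superpose_rmsd,
)
from gofold.engine import Trajectory


from tests_oracles import quaternion_rmsd


def random_rotation(rng):
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q


class TestSuperposition:
    def test_identical_coordinates_give_zero(self, rng):
        X = rng.normal(size=(20, 3))
        assert superpose_rmsd(X, X)[0] == pytest.approx(0.0, abs=1e-12)

    def test_rigid_transform_gives_zero(self, rng):
        X = rng.normal(size=(30, 3))
        Y = X @ random_rotation(rng).T + np.array([1.0, -2.0, 3.0])
        assert superpose_rmsd(X, Y)[0] == pytest.approx(0.0, abs=1e-10)

    def test_matches_quaternion_oracle(self, rng):
        for _ in range(5):
            X = rng.normal(size=(50, 3))
            Y = rng.normal(size=(50, 3))
            assert superpose_rmsd(X, Y)[0] == pytest.approx(quaternion_rmsd(X, Y), abs=1e-10)

    def test_degenerate_selection_rejected(self):
        X = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])  # collinear
        with pytest.raises(ValueError, match="degenerate"):
            superpose_rmsd(X, X + 1.0)

    def test_rmsd_is_a_metric_on_random_triples(self, rng):
        A, B, C = (rng.normal(size=(15, 3)) for _ in range(3))
        dab = superpose_rmsd(A, B)[0]
        dba = superpose_rmsd(B, A)[0]
        dac = superpose_rmsd(A, C)[0]
        dbc = superpose_rmsd(B, C)[0]
        assert dab == pytest.approx(dba, abs=1e-9)
        assert dac <= dab + dbc + 1e-9


class TestSimpleGeometry:
    def test_rg_single_atom_zero(self):
        assert radius_of_gyration(np.zeros((1, 3))) == 0.0

    def test_rg_two_atoms_half_distance(self):
        X = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        assert radius_of_gyration(X) == pytest.approx(0.5)

    def test_omega_trans_cis_and_right_angle(self, helix_minifold):
        atoms = helix_minifold.model.atoms
        lookup = {(a.residue_index, a.name): a.index for a in atoms}
        n = len(atoms)
        X = np.zeros((n, 3))
        # construct an explicit geometry for residues 1-2
        X[lookup[(1, "CA")]] = [0.0, 1.0, 0.0]
        X[lookup[(1, "C")]] = [0.0, 0.0, 0.0]
        X[lookup[(2, "N")]] = [1.0, 0.0, 0.0]
        X[lookup[(2, "CA")]] = [1.0, -1.0, 0.0]   # trans
        assert peptide_omega(atoms, X, 1, 2) == pytest.approx(180.0)
        X[lookup[(2, "CA")]] = [1.0, 1.0, 0.0]    # cis
        assert peptide_omega(atoms, X, 1, 2) == pytest.approx(0.0)
        X[lookup[(2, "CA")]] = [1.0, 0.0, 1.0]
        # right-angle construction; sign fixed by the cross-product convention
        assert abs(peptide_omega(atoms, X, 1, 2)) == pytest.approx(90.0)

    def test_omega_missing_atom_raises(self, helix_minifold):
        atoms = [a for a in helix_minifold.model.atoms if a.name != "C" or a.residue_index != 1]
        X = np.zeros((len(atoms), 3))
        with pytest.raises(ValueError, match="missing backbone atom"):
            peptide_omega(atoms, X, 1, 2)


class TestEnsembles:
    def _traj(self, energies, frames):
        t = Trajectory()
        t.energy = list(energies)
        t.frames = [np.asarray(f, dtype=float) for f in frames]
        t.event_index = list(range(len(t.energy)))
        return t

    def test_stride_one_keeps_all_frames(self, rng):
        frames = rng.normal(size=(7, 5, 3))
        ens = build_ensemble([self._traj(np.zeros(7), frames)], stride=1)
        assert len(ens) == 7

    def test_never_folded_trajectory_is_empty(self, rng):
        frames = rng.normal(size=(5, 4, 3))
        traj = self._traj([0.0] * 5, frames)
        with pytest.raises(ValueError, match="empty ensemble"):
            build_ensemble([traj], folded_energy_threshold=-10.0)

    def test_equilibration_drops_prefolding_frames(self, rng):
        E = [0.0, -2.0, -12.0, -5.0, -13.0]
        frames = rng.normal(size=(5, 4, 3))
        ens = build_ensemble([self._traj(E, frames)], folded_energy_threshold=-10.0)
        assert len(ens) == 3  # frames from the first E <= -10 onwards
        assert np.array_equal(ens.frames[0], frames[2])


class TestClustering:
    def test_single_frame_single_cluster(self, rng):
        ens = ConformationEnsemble(rng.normal(size=(1, 8, 3)))
        res = cluster_kmeans(ens, target_radius=1.0, seed=0)
        assert res.k == 1 and res.representatives[0] == 0

    def test_radius_larger_than_diameter_gives_one_cluster(self, rng):
        ens = ConformationEnsemble(rng.normal(scale=0.01, size=(10, 8, 3)))
        res = cluster_kmeans(ens, target_radius=100.0, seed=0)
        assert res.k == 1

    def test_planted_families_recovered_exactly(self, rng):
        base = rng.normal(size=(12, 3)) * 4.0
        other = rng.normal(size=(12, 3)) * 4.0 + 30.0
        fam1 = base[None] + rng.normal(scale=0.05, size=(10, 12, 3))
        fam2 = other[None] + rng.normal(scale=0.05, size=(10, 12, 3))
        ens = ConformationEnsemble(np.concatenate([fam1, fam2]))
        res = cluster_kmeans(ens, target_radius=2.0, seed=0)
        assert res.k == 2
        labels = res.labels
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[10]
        assert res.max_radius <= 2.0

    def test_nonpositive_radius_rejected(self, rng):
        ens = ConformationEnsemble(rng.normal(size=(3, 5, 3)))
        with pytest.raises(ValueError):
            cluster_kmeans(ens, target_radius=0.0)

    def test_deterministic_under_seed(self, rng):
        ens = ConformationEnsemble(rng.normal(size=(12, 6, 3)))
        a = cluster_kmeans(ens, target_radius=3.0, seed=5)
        b = cluster_kmeans(ens, target_radius=3.0, seed=5)
        assert np.array_equal(a.labels, b.labels)


class TestSasa:
    def test_isolated_atom_full_sphere(self):
        out = sasa_per_atom(np.zeros((1, 3)), np.array([1.7]))
        assert out[0] == pytest.approx(4 * math.pi * (1.7 + 1.4) ** 2, rel=1e-6)

    def test_far_separated_atoms_additive(self):
        X = np.array([[0.0, 0, 0], [50.0, 0, 0]])
        r = np.array([1.7, 1.5])
        out = sasa_per_atom(X, r)
        iso = [4 * math.pi * (ri + 1.4) ** 2 for ri in r]
        assert out == pytest.approx(iso, rel=1e-6)

    def test_overlapping_pair_matches_spherical_cap_formula(self):
        # two equal spheres: exposed fraction has the exact closed form
        # A = 2*pi*R*(R + d/2 - ... ) -> fraction = (1 + d/(2R))/2 per sphere
        r, probe, d = 1.7, 1.4, 2.0
        R = r + probe
        X = np.array([[0.0, 0, 0], [d, 0, 0]])
        out = sasa_per_atom(X, np.array([r, r]), probe)
        frac = (1.0 + d / (2 * R)) / 2.0
        exact = 4 * math.pi * R**2 * frac
        assert out[0] == pytest.approx(exact, rel=0.01)
        assert out[1] == pytest.approx(exact, rel=0.01)

    def test_burying_monotonicity(self, rng):
        """Adding an atom never increases another atom's exposed area."""
        X = rng.normal(scale=2.0, size=(6, 3))
        r = np.full(6, 1.7)
        before = sasa_per_atom(X[:5], r[:5])
        after = sasa_per_atom(X, r)
        assert np.all(after[:5] <= before + 1e-9)

    def test_zero_radius_rejected(self):
        with pytest.raises(ValueError):
            sasa_per_atom(np.zeros((1, 3)), np.array([0.0]))

    def test_ratio_profile_flags_displaced_residue(self, minifold):
        m = minifold.model
        native = m.positions
        moved = native.copy()
        target = max(a.residue_index for a in m.atoms)
        idx = [a.index for a in m.atoms if a.residue_index == target]
        moved[idx] += 40.0  # expose the last residue fully
        ens = ConformationEnsemble(moved[None])
        prof = sasa_ratio_profile(ens, native, m.atoms)
        assert prof[target]["ratio"] > 1.05
        # the displaced residue gains the most exposure; residues it used to
        # bury may gain a little, none may lose
        others = [prof[r]["ratio"] for r in prof if r != target and not prof[r]["undefined"]]
        assert prof[target]["ratio"] > max(others)
        assert min(others) > 0.99

    def test_identity_ensemble_all_ratios_one(self, minifold):
        m = minifold.model
        ens = ConformationEnsemble(m.positions[None])
        prof = sasa_ratio_profile(ens, m.positions, m.atoms)
        for r, entry in prof.items():
            if not entry["undefined"]:
                assert entry["ratio"] == pytest.approx(1.0)


class TestContactsAndPopulations:
    def test_native_frame_ratios_are_one(self, minifold):
        m = minifold.model
        ens = ConformationEnsemble(m.positions[None])
        cmap = contact_ratio_map(ens, m.contacts, m.atoms)
        assert all(v == pytest.approx(1.0) for v in cmap.values())

    def test_blown_apart_frame_ratios_are_zero(self, minifold):
        m = minifold.model
        ens = ConformationEnsemble((m.positions * 20.0)[None])
        cmap = contact_ratio_map(ens, m.contacts, m.atoms)
        assert all(v == 0.0 for v in cmap.values())

    def test_matches_per_frame_brute_force(self, minifold, rng):
        m = minifold.model
        frames = m.positions[None] + rng.normal(scale=0.4, size=(4,) + m.positions.shape)
        ens = ConformationEnsemble(frames)
        cmap = contact_ratio_map(ens, m.contacts, m.atoms)
        # brute force with explicit loops
        from collections import defaultdict
        nat = defaultdict(int)
        formed = defaultdict(float)
        for (i, j), sig in zip(m.contacts.pairs, m.contacts.sigma):
            rp = tuple(sorted((m.atoms[i].residue_index, m.atoms[j].residue_index)))
            nat[rp] += 1
            for fr in frames:
                d = np.linalg.norm(fr[i] - fr[j])
                if sig - 1e-12 <= d < m.contacts.lam * sig:
                    formed[rp] += 1
        for rp in nat:
            assert cmap[rp] == pytest.approx(formed[rp] / (4 * nat[rp]))

    def test_population_windows(self):
        basins = MacrostateDefinition({"native": (-50.0, -30.0), "denat": (-10.0, 0.0)})
        E = np.array([-45.0, -40.0, -35.0, -20.0, -5.0])
        pops = macrostate_populations(E, basins)
        assert pops["native"] == pytest.approx(0.6)
        assert pops["denat"] == pytest.approx(0.2)
        assert sum(pops.values()) <= 1.0

    def test_two_state_sampler_weights_recovered(self):
        from gofold.synthetic import make_two_state_samples, two_state_stats
        T = 6.0
        samples = make_two_state_samples(-40.0, 0.0, [T], n=50_000, seed=2,
                                         g_unfolded=200.0)[T]
        p_exact = two_state_stats(T, -40.0, 0.0, 1.0, 200.0)[0]
        basins = MacrostateDefinition({"folded": (-41.0, -39.0), "unfolded": (-1.0, 1.0)})
        pops = macrostate_populations(samples, basins)
        # binomial standard error
        se = math.sqrt(p_exact * (1 - p_exact) / 50_000)
        assert pops["folded"] == pytest.approx(p_exact, abs=4 * se)

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            MacrostateDefinition({"a": (0.0, 2.0), "b": (1.0, 3.0)})


class TestNonpolarSolvation:
    def test_zero_sasa_gives_intercept(self):
        assert nonpolar_solvation(0.0) == pytest.approx(3.8)

    def test_one_nm2(self):
        assert nonpolar_solvation(1.0) == pytest.approx(6.0)

    def test_linearity(self):
        S = 7.3
        assert nonpolar_solvation(2 * S) - nonpolar_solvation(S) == pytest.approx(2.2 * S)

    def test_negative_sasa_rejected(self):
        with pytest.raises(ValueError):
            nonpolar_solvation(-1.0)
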