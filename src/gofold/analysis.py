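"""Geometric observables and ensemble analyses.

Covers optimal (Kabsch) superposition and RMSD, radius of gyration,
Shrake-Rupley solvent-accessible surface area, peptide omega dihedrals,
equilibrated-ensemble construction, k-means structural clustering with a
target cluster radius, native-contact ratio maps, macrostate populations
from energy windows, and the affine nonpolar solvation-energy estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .structure import AtomRecord, NativeContactSet

__all__ = [
    "ConformationEnsemble",
    "ClusterResult",
    "MacrostateDefinition",
    "superpose_rmsd",
    "apply_superposition",
    "radius_of_gyration",
    "build_ensemble",
    "cluster_kmeans",
    "sasa_per_atom",
    "sasa_per_residue",
    "sasa_ratio_profile",
    "peptide_omega",
    "contact_ratio_map",
    "macrostate_populations",
    "nonpolar_solvation",
]


@dataclass
class ConformationEnsemble:
    """Frames (M, N, 3) with provenance; all frames share one atom count."""

    frames: np.ndarray
    temperature: float | None = None
    stride_events: int = 1
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (M, N, 3)")
        if self.stride_events < 1:
            raise ValueError("stride must be >= 1")

    def __len__(self) -> int:
        return self.frames.shape[0]


@dataclass
class ClusterResult:
    labels: np.ndarray          # (M,) cluster id per frame
    representatives: np.ndarray  # (k,) medoid frame indices
    k: int
    target_radius: float
    max_radius: float           # largest frame-to-representative RMSD realised


@dataclass
class MacrostateDefinition:
    """Named energy windows (inclusive lo, exclusive hi), e.g. basins of F(E)."""

    windows: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        items = sorted(self.windows.items(), key=lambda kv: kv[1])
        for (la, (a0, a1)), (lb, (b0, b1)) in zip(items, items[1:]):
            if b0 < a1:
                raise ValueError(f"windows {la!r} and {lb!r} overlap")


# --------------------------------------------------------------------------
# superposition / simple geometry
# --------------------------------------------------------------------------

def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rotation R and centroids such that R@(P-cP)+cQ best fits Q."""
    cP = P.mean(axis=0)
    cQ = Q.mean(axis=0)
    H = (P - cP).T @ (Q - cQ)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, cP, cQ


def superpose_rmsd(
    X: np.ndarray, Y: np.ndarray, selection: np.ndarray | None = None
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares optimal superposition of X onto Y.

    Returns ``(rmsd, R, cX, cY)`` where the fitted coordinates are
    ``(X - cX) @ R.T + cY``; the RMSD is evaluated over ``selection``
    (all atoms when omitted).  Degenerate selections (fewer than 3 atoms,
    collinear or coincident) raise ``ValueError``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError("coordinate arrays must have equal shapes")
    sel = np.arange(X.shape[0]) if selection is None else np.asarray(selection)
    P, Q = X[sel], Y[sel]
    if P.shape[0] < 3:
        raise ValueError("selection must contain at least 3 atoms")
    if np.linalg.matrix_rank(P - P.mean(axis=0), tol=1e-9) < 2:
        raise ValueError("degenerate (collinear or coincident) selection")
    R, cP, cQ = _kabsch(P, Q)
    fitted = (P - cP) @ R.T + cQ
    rmsd = math.sqrt(float(np.mean(np.sum((fitted - Q) ** 2, axis=1))))
    return rmsd, R, cP, cQ


def apply_superposition(X: np.ndarray, R: np.ndarray, cX: np.ndarray, cY: np.ndarray) -> np.ndarray:
    return (np.asarray(X, dtype=float) - cX) @ R.T + cY


def radius_of_gyration(X: np.ndarray) -> float:
    """RMS distance from the unit-mass centroid, Å."""
    X = np.asarray(X, dtype=float)
    c = X.mean(axis=0)
    return math.sqrt(float(np.mean(np.sum((X - c) ** 2, axis=1))))


def peptide_omega(atoms: list[AtomRecord], X: np.ndarray, res_i: int, res_j: int) -> float:
    """Signed peptide dihedral CA(i)-C(i)-N(j)-CA(j) in degrees, (-180, 180].

    ~180° for a trans peptide bond, ~0° for cis.
    """
    if res_j != res_i + 1:
        raise ValueError("residues must be adjacent")
    lookup = {(a.residue_index, a.name): a.index for a in atoms}
    try:
        idx = [lookup[(res_i, "CA")], lookup[(res_i, "C")],
               lookup[(res_j, "N")], lookup[(res_j, "CA")]]
    except KeyError as exc:
        raise ValueError(f"missing backbone atom for omega dihedral: {exc}") from exc
    p = np.asarray(X, dtype=float)[idx]
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    angle = math.degrees(math.atan2(float(m1 @ n2), float(n1 @ n2)))
    return 180.0 if angle == -180.0 else angle


# --------------------------------------------------------------------------
# ensembles
# --------------------------------------------------------------------------

def build_ensemble(
    trajectories,
    stride: int = 1,
    folded_energy_threshold: float | None = None,
    temperature: float | None = None,
) -> ConformationEnsemble:
    """Equilibrated, decorrelated frames from one or more trajectories.

    When ``folded_energy_threshold`` is given, all frames before the first
    folding transition (first sample with E <= threshold) are dropped from each
    trajectory; every ``stride``-th surviving frame is kept.
    """
    frames = []
    for traj in np.atleast_1d(trajectories):
        if not traj.frames:
            continue
        E = np.asarray(traj.energy)
        start = 0
        if folded_energy_threshold is not None:
            below = np.nonzero(E <= folded_energy_threshold)[0]
            if below.size == 0:
                continue  # this trajectory never folds
            start = int(below[0])
        frames.extend(traj.frames[start::stride])
    if not frames:
        raise ValueError("empty ensemble: no frame passes the equilibration rule")
    return ConformationEnsemble(np.stack(frames), temperature=temperature,
                                stride_events=stride)


def superpose_ensemble(ensemble: ConformationEnsemble, reference: np.ndarray,
                       selection: np.ndarray | None = None) -> np.ndarray:
    """All frames fitted onto ``reference``; returns the fitted (M, N, 3) array."""
    out = np.empty_like(ensemble.frames)
    for m, frame in enumerate(ensemble.frames):
        _, R, cX, cY = superpose_rmsd(frame, reference, selection)
        out[m] = apply_superposition(frame, R, cX, cY)
    return out


def cluster_kmeans(
    ensemble: ConformationEnsemble,
    target_radius: float,
    seed: int = 0,
    max_k: int | None = None,
) -> ClusterResult:
    """k-means structural clustering with a target cluster radius.

    Frames are mutually superposed (onto the first frame), flattened and
    clustered; k grows from 1 until every frame lies within ``target_radius``
    (RMSD) of its cluster's medoid representative.
    """
    if target_radius <= 0:
        raise ValueError("cluster radius must be positive")
    M = len(ensemble)
    fitted = superpose_ensemble(ensemble, ensemble.frames[0])
    flat = fitted.reshape(M, -1)
    n_atoms = ensemble.frames.shape[1]
    max_k = M if max_k is None else min(max_k, M)

    def frame_rmsd(a: int, b: int) -> float:
        return superpose_rmsd(ensemble.frames[a], ensemble.frames[b])[0]

    best = None
    for k in range(1, max_k + 1):
        km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(flat)
        labels = km.labels_
        reps = np.empty(k, dtype=int)
        max_r = 0.0
        for c in range(k):
            members = np.nonzero(labels == c)[0]
            # medoid: member closest to the cluster centroid in fitted space
            dc = np.linalg.norm(flat[members] - km.cluster_centers_[c], axis=1)
            reps[c] = members[int(np.argmin(dc))]
            for m in members:
                max_r = max(max_r, frame_rmsd(int(m), int(reps[c])))
        best = ClusterResult(labels=labels, representatives=reps, k=k,
                             target_radius=target_radius, max_radius=max_r)
        if max_r <= target_radius:
            break
    return best


# --------------------------------------------------------------------------
# solvent accessible surface area (Shrake-Rupley)
# --------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


_N_SPHERE_POINTS = 960
_UNIT_SPHERE = _sphere_points(_N_SPHERE_POINTS)


def sasa_per_atom(X: np.ndarray, radii: np.ndarray, probe: float = 1.4) -> np.ndarray:
    """Shrake-Rupley SASA per atom (Å²), 960 test points per atom."""
    X = np.asarray(X, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("all radii must be positive")
    n = X.shape[0]
    ext = radii + probe
    out = np.empty(n)
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    for i in range(n):
        cut = (ext[i] + ext) ** 2
        nbr = np.nonzero((d2[i] < cut) & (np.arange(n) != i))[0]
        pts = X[i] + ext[i] * _UNIT_SPHERE
        exposed = np.ones(_N_SPHERE_POINTS, dtype=bool)
        for j in nbr:
            exposed &= np.sum((pts - X[j]) ** 2, axis=1) > ext[j] ** 2
            if not exposed.any():
                break
        out[i] = 4.0 * math.pi * ext[i] ** 2 * exposed.sum() / _N_SPHERE_POINTS
    return out


def sasa_per_residue(
    X: np.ndarray, atoms: list[AtomRecord], probe: float = 1.4
) -> dict[int, float]:
    radii = np.array([a.vdw_radius for a in atoms])
    per_atom = sasa_per_atom(X, radii, probe)
    out: dict[int, float] = {}
    for a, s in zip(atoms, per_atom):
        out[a.residue_index] = out.get(a.residue_index, 0.0) + float(s)
    return out


def sasa_ratio_profile(
    ensemble: ConformationEnsemble,
    native: np.ndarray,
    atoms: list[AtomRecord],
    probe: float = 1.4,
) -> dict[int, dict]:
    """Per-residue mean SASA over the ensemble divided by the native SASA.

    Residues with zero native SASA get ``ratio = inf`` and are flagged so they
    can be excluded from percentage summaries.  Standard errors of the mean
    ratio are reported alongside.
    """
    native_sasa = sasa_per_residue(native, atoms, probe)
    residues = sorted(native_sasa)
    per_frame = np.array([
        [sasa_per_residue(fr, atoms, probe)[r] for r in residues]
        for fr in ensemble.frames
    ])
    mean = per_frame.mean(axis=0)
    sem = per_frame.std(axis=0, ddof=1) / math.sqrt(len(ensemble)) if len(ensemble) > 1 \
        else np.zeros(len(residues))
    out: dict[int, dict] = {}
    for k, r in enumerate(residues):
        nat = native_sasa[r]
        if nat <= 0.0:
            out[r] = {"ratio": math.inf, "sem": math.inf, "undefined": True}
        else:
            out[r] = {"ratio": float(mean[k] / nat), "sem": float(sem[k] / nat),
                      "undefined": False}
    return out


# --------------------------------------------------------------------------
# contacts / populations / solvation
# --------------------------------------------------------------------------

def contact_ratio_map(
    ensemble: ConformationEnsemble,
    contacts: NativeContactSet,
    atoms: list[AtomRecord],
) -> dict[tuple[int, int], float]:
    """Mean fraction of native atomic contacts formed, per residue pair.

    For each residue pair the per-frame count of formed native atomic contacts
    (distance inside ``[sigma, lambda*sigma)``) is divided by the native-state
    count; the mean over frames is returned.
    """
    idx = np.array(contacts.pairs, dtype=int).reshape(-1, 2)
    res_pair = [
        tuple(sorted((atoms[i].residue_index, atoms[j].residue_index)))
        for i, j in contacts.pairs
    ]
    native_counts: dict[tuple[int, int], int] = {}
    for rp in res_pair:
        native_counts[rp] = native_counts.get(rp, 0) + 1
    sums = {rp: 0.0 for rp in native_counts}
    lo = contacts.sigma
    hi = contacts.lam * contacts.sigma
    for frame in ensemble.frames:
        d = np.linalg.norm(frame[idx[:, 0]] - frame[idx[:, 1]], axis=1)
        formed = (d >= lo - 1e-12) & (d < hi)
        for rp, f in zip(res_pair, formed):
            if f:
                sums[rp] += 1.0
    M = len(ensemble)
    return {rp: sums[rp] / (M * native_counts[rp]) for rp in native_counts}


def macrostate_populations(
    samples: np.ndarray, basins: MacrostateDefinition
) -> dict[str, float]:
    """Fraction of energy samples inside each basin window.

    Samples falling in none of the windows (e.g. on barrier tops) remain
    unassigned, so the fractions sum to at most 1.
    """
    E = np.asarray(samples, dtype=float)
    out = {}
    for name, (lo, hi) in basins.windows.items():
        out[name] = float(np.mean((E >= lo) & (E < hi)))
    return out


def nonpolar_solvation(total_sasa_nm2: float, gamma: float = 2.2, beta: float = 3.8) -> float:
    """Affine nonpolar solvation free energy, kJ/mol.

    ``G = gamma * SASA + beta`` with gamma in kJ mol^-1 nm^-2 and SASA in nm².
    """
    if total_sasa_nm2 < 0:
        raise ValueError("SASA must be non-negative")
    return gamma * total_sasa_nm2 + beta
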