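"""Desk-scale synthetic systems with known ground truth.

These generators exercise every pipeline stage without external input:

* a two-particle square-well system in a reflecting box, with the exact
  canonical mean potential energy from configuration-volume ratios;
* a foldable "minifold" — an ideal poly-glycine α-helix emitted as PDB text,
  small enough for long event-driven runs yet touching every model rule
  (residue-separation contact rule, bond wells, covalent-like pseudo-bonds);
* exact Boltzmann-weighted samples of a two-level system (oracle for WHAM,
  heat capacity and populations);
* Gaussian ensembles with a prescribed covariance (oracle for PCA).

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .analysis import ConformationEnsemble
from .engine import PairTables, _CONTACT, _NONE
from .structure import AtomRecord, StructureModel, write_pdb

__all__ = [
    "TwoParticleSystem",
    "MinifoldSpec",
    "make_two_particle_system",
    "make_minifold",
    "make_two_state_samples",
    "two_state_stats",
    "make_gaussian_ensemble",
]


# --------------------------------------------------------------------------
# two-particle square-well oracle
# --------------------------------------------------------------------------

def _wall_weighted_ball_volume(R: float, L: float) -> float:
    """∫_{|Δ|<R} (L-|Δx|)(L-|Δy|)(L-|Δz|) dΔ for R <= L.

    This is the exact configuration-space weight of relative separations below
    R for two independent points uniform in a cube of side L.
    """
    if R > L:
        raise ValueError("radius exceeds box side")
    return 8.0 * (
        L**3 * math.pi * R**3 / 6.0
        - 3.0 * L**2 * math.pi * R**4 / 16.0
        + L * R**5 / 5.0
        - R**6 / 48.0
    )


@dataclass
class TwoParticleSystem:
    tables: PairTables
    positions: np.ndarray
    sigma: float
    lam: float
    box: float

    def mean_potential(self, T: float) -> float:
        """Exact canonical <U>(T): well weight vs free weight in the box."""
        F_sig = _wall_weighted_ball_volume(self.sigma, self.box)
        F_lam = _wall_weighted_ball_volume(self.lam * self.sigma, self.box)
        W_well = F_lam - F_sig
        W_free = self.box**6 - F_lam
        w = W_well * math.exp(1.0 / T)
        return -w / (w + W_free)


def make_two_particle_system(
    box_side: float, sigma: float = 1.0, lam: float = 1.6
) -> TwoParticleSystem:
    """Two unit-mass atoms with one square well, in a reflecting cubic box."""
    if lam * sigma >= box_side:
        raise ValueError("well must fit inside the box")
    code = np.full((2, 2), _CONTACT, dtype=np.int8)
    np.fill_diagonal(code, _NONE)
    din = np.full((2, 2), sigma)
    dout = np.full((2, 2), lam * sigma)
    tables = PairTables(code=code, din=din, dout=dout,
                        contact_index=np.array([[0, 1]], dtype=np.int64))
    mid = 0.5 * (sigma + lam * sigma)
    c = box_side / 2.0
    positions = np.array([[c - mid / 2, c, c], [c + mid / 2, c, c]])
    return TwoParticleSystem(tables=tables, positions=positions,
                             sigma=sigma, lam=lam, box=box_side)


# --------------------------------------------------------------------------
# minifold
# --------------------------------------------------------------------------

# ideal backbone geometry (lengths Å, angles deg)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8
_PHI_HELIX, _PSI_HELIX = -57.0, -47.0


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension-of-reference-frame placement of atom D after A-B-C."""
    th = math.radians(angle_deg)
    ph = math.radians(torsion_deg)
    d2 = np.array([-bond * math.cos(th),
                   bond * math.sin(th) * math.cos(ph),
                   bond * math.sin(th) * math.sin(ph)])
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.column_stack([bc, np.cross(n, bc), n])
    return c + m @ d2


_PHI_STRAND, _PSI_STRAND = -139.0, 135.0
# hairpin turn dihedrals: chosen once (grid search over clash-free turns) to
# maximise the number of cross-strand contacts of the resulting fold
_TURN_DIHEDRALS = ((120.0, 90.0), (60.0, -30.0))


def backbone_from_dihedrals(phis, psis) -> np.ndarray:
    """Backbone (N, CA, C, O per residue) from per-residue (phi, psi), ω=180."""
    n_res = len(phis)
    N = [np.zeros(3)]
    CA = [np.array([_B_N_CA, 0.0, 0.0])]
    th = math.radians(180.0 - _A_N_CA_C)
    C = [CA[0] + _B_CA_C * np.array([math.cos(th), math.sin(th), 0.0])]
    O: list[np.ndarray] = []
    for i in range(n_res - 1):
        N.append(_place_atom(N[i], CA[i], C[i], _B_C_N, _A_CA_C_N, psis[i]))
        CA.append(_place_atom(CA[i], C[i], N[i + 1], _B_N_CA, _A_C_N_CA, 180.0))
        C.append(_place_atom(C[i], N[i + 1], CA[i + 1], _B_CA_C, _A_N_CA_C, phis[i + 1]))
        O.append(_place_atom(N[i + 1], CA[i], C[i], _B_C_O, _A_CA_C_O, 180.0))
    O.append(_place_atom(N[-1], CA[-1], C[-1], _B_C_O, _A_CA_C_O, psis[-1] + 180.0))
    coords = []
    for i in range(n_res):
        coords.extend([N[i], CA[i], C[i], O[i]])
    return np.array(coords)


def helix_backbone(n_res: int, phi: float = _PHI_HELIX, psi: float = _PSI_HELIX) -> np.ndarray:
    """Ideal α-helical backbone: (4*n_res, 3) array."""
    return backbone_from_dihedrals([phi] * n_res, [psi] * n_res)


def hairpin_backbone(n_res: int) -> np.ndarray:
    """Antiparallel two-strand hairpin: strands at ideal β dihedrals joined by
    a two-residue turn; nearly all native contacts are cross-strand, which
    makes folding cooperative (two-state)."""
    half = (n_res - 2) // 2
    phis = [_PHI_STRAND] * n_res
    psis = [_PSI_STRAND] * n_res
    (phis[half], psis[half]), (phis[half + 1], psis[half + 1]) = _TURN_DIHEDRALS
    return backbone_from_dihedrals(phis, psis)


@dataclass
class MinifoldSpec:
    n_beads: int
    seed: int
    pdb_text: str
    model: StructureModel
    topology: str = "hairpin"

    @property
    def native_energy(self) -> float:
        return self.model.native_energy


def make_minifold(n_beads: int, seed: int = 0, jitter: float = 0.02,
                  max_retries: int = 5, topology: str = "hairpin") -> MinifoldSpec:
    """Compact foldable test protein emitted as PDB text.

    ``topology="hairpin"`` (default) builds an antiparallel poly-Gly β-hairpin
    whose native contacts are almost entirely cross-strand, giving a
    cooperative, two-basin (folded/unfolded) equilibrium; ``"helix"`` builds
    an ideal α-helix, whose local O(i)···N(i+3, i+4) contact pattern melts
    gradually.  The native state is clash-free with at least ``n_beads``
    native contacts, and the structure is re-parsed through the standard
    loaders so the generated fixture passes exactly the same validation as
    real input.  Deterministic under ``seed`` (used for the coordinate
    jitter).
    """
    if n_beads < 6:
        raise ValueError("need at least 6 residues for a foldable minifold")
    builders = {"hairpin": hairpin_backbone, "helix": helix_backbone}
    if topology not in builders:
        raise ValueError(f"unknown topology {topology!r}")
    rng = np.random.default_rng(seed)
    last_err: Exception | None = None
    for attempt in range(max_retries):
        coords = builders[topology](n_beads)
        scale = jitter / (2.0**attempt)
        coords = coords + rng.uniform(-scale, scale, size=coords.shape)
        atoms = []
        names = ["N", "CA", "C", "O"]
        elements = ["N", "C", "C", "O"]
        for i in range(n_beads):
            for k in range(4):
                atoms.append(AtomRecord(
                    index=4 * i + k, name=names[k], element=elements[k],
                    residue_index=i + 1, residue_name="GLY", chain="A",
                    position=coords[4 * i + k],
                ))
        pdb_text = write_pdb(atoms)
        try:
            model = StructureModel.from_pdb(pdb_text, chain="A")
        except ValueError as exc:
            last_err = exc
            continue
        if len(model.contacts) < n_beads:
            last_err = ValueError("too few native contacts in generated fold")
            continue
        return MinifoldSpec(n_beads=n_beads, seed=seed, pdb_text=pdb_text,
                            model=model, topology=topology)
    raise RuntimeError(f"failed to generate a clash-free minifold: {last_err}")


# --------------------------------------------------------------------------
# two-level system and Gaussian ensembles
# --------------------------------------------------------------------------

def two_state_stats(T: float, E_folded: float, E_unfolded: float,
                    g_folded: float = 1.0, g_unfolded: float = 1.0):
    """Closed-form (p_folded, <E>, Cv) of the two-level system at T."""
    d = E_unfolded - E_folded
    w = (g_unfolded / g_folded) * math.exp(-d / T)
    p = 1.0 / (1.0 + w)
    mean = p * E_folded + (1.0 - p) * E_unfolded
    cv = p * (1.0 - p) * d * d / T**2
    return p, mean, cv


def make_two_state_samples(
    E_folded: float, E_unfolded: float, temps, n: int, seed: int = 0,
    g_folded: float = 1.0, g_unfolded: float = 1.0,
) -> dict[float, np.ndarray]:
    """Exact Boltzmann-weighted energy draws at each temperature."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    out = {}
    for T in temps:
        if T <= 0:
            raise ValueError("temperatures must be positive")
        p, _, _ = two_state_stats(T, E_folded, E_unfolded, g_folded, g_unfolded)
        out[float(T)] = np.where(rng.random(n) < p, E_folded, E_unfolded).astype(float)
    return out


def make_gaussian_ensemble(
    covariance: np.ndarray, mean_structure: np.ndarray, n: int, seed: int = 0
) -> ConformationEnsemble:
    """Frames drawn with the specified 3n x 3n covariance about a mean."""
    mean = np.asarray(mean_structure, dtype=float)
    cov = np.asarray(covariance, dtype=float)
    dim = mean.size
    if cov.shape != (dim, dim):
        raise ValueError("covariance must be (3n, 3n) for an (n, 3) mean")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    evals = np.linalg.eigvalsh(cov)
    if evals.min() < -1e-8 * max(evals.max(), 1.0):
        raise ValueError("covariance must be positive semidefinite")
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(np.zeros(dim), cov, size=n, method="eigh")
    frames = mean[None, :, :] + draws.reshape(n, -1, 3)
    return ConformationEnsemble(frames)
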