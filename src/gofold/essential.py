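"""Essential dynamics: Cα covariance matrices, principal modes and RMSF.

Frames are optimally superposed onto a reference structure before deviations
are accumulated, giving a non-mass-weighted 3n x 3n positional covariance
matrix whose trace is the total mean square fluctuation (MSF) in Å².  The
leading eigenvectors (principal components) capture the dominant collective
motions; per-atom RMSF profiles within the top-k mode subspace localise them
along the chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .analysis import ConformationEnsemble, apply_superposition, superpose_rmsd

__all__ = ["CovarianceResult", "covariance_matrix", "principal_modes", "rmsf_along_modes"]


@dataclass
class CovarianceResult:
    matrix: np.ndarray        # (3n, 3n), Å²
    eigenvalues: np.ndarray   # descending
    eigenvectors: np.ndarray  # columns, matching eigenvalue order
    deviations: np.ndarray    # (M, 3n) superposed deviations used
    selection: np.ndarray     # atom indices the covariance covers
    total_msf: float          # trace, Å²

    @property
    def n_atoms(self) -> int:
        return self.selection.size


def covariance_matrix(
    ensemble: ConformationEnsemble,
    reference: np.ndarray,
    selection: np.ndarray | None = None,
    deviations_from: str = "mean",
) -> CovarianceResult:
    """Positional covariance after superposition onto ``reference``.

    ``selection`` restricts both the superposition fit and the covariance to a
    subset (typically the Cα atoms).  Deviations are taken from the ensemble
    mean by default; ``deviations_from="reference"`` uses the reference
    coordinates instead.
    """
    M = len(ensemble)
    if M < 2:
        raise ValueError("need at least 2 frames for a covariance matrix")
    reference = np.asarray(reference, dtype=float)
    sel = np.arange(reference.shape[0]) if selection is None else np.asarray(selection)
    fitted = np.empty((M, sel.size, 3))
    for m, frame in enumerate(ensemble.frames):
        _, R, cX, cY = superpose_rmsd(frame, reference, sel)
        fitted[m] = apply_superposition(frame, R, cX, cY)[sel]
    origin = fitted.mean(axis=0) if deviations_from == "mean" else reference[sel]
    dev = (fitted - origin).reshape(M, -1)
    cov = dev.T @ dev / M
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return CovarianceResult(
        matrix=cov, eigenvalues=evals[order], eigenvectors=evecs[:, order],
        deviations=dev, selection=sel, total_msf=float(np.trace(cov)),
    )


def principal_modes(cov: CovarianceResult, k: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Top-k eigenpairs and the fraction of total MSF they carry."""
    dim = cov.eigenvalues.size
    if not (1 <= k <= dim):
        raise ValueError(f"k must be in [1, {dim}]")
    evals = cov.eigenvalues[:k]
    evecs = cov.eigenvectors[:, :k]
    fraction = float(evals.sum() / cov.total_msf) if cov.total_msf > 0 else 0.0
    return evals, evecs, fraction


def rmsf_along_modes(cov: CovarianceResult, k: int) -> np.ndarray:
    """Per-atom RMSF (Å) of the motion projected onto the top-k mode subspace."""
    _, evecs, _ = principal_modes(cov, k)
    proj = cov.deviations @ evecs           # (M, k)
    recon = proj @ evecs.T                  # (M, 3n)
    per_atom = recon.reshape(recon.shape[0], -1, 3)
    return np.sqrt(np.mean(np.sum(per_atom**2, axis=2), axis=0))
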