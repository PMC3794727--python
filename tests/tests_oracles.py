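"""Independent numerical oracles shared across test modules."""

import math

import numpy as np


def quaternion_rmsd(X, Y):
    """Optimal-superposition RMSD via Horn's quaternion eigenvector method,
    independent of the SVD (Kabsch) implementation under test."""
    P = X - X.mean(axis=0)
    Q = Y - Y.mean(axis=0)
    Sxx, Sxy, Sxz = (P[:, 0] @ Q[:, 0]), (P[:, 0] @ Q[:, 1]), (P[:, 0] @ Q[:, 2])
    Syx, Syy, Syz = (P[:, 1] @ Q[:, 0]), (P[:, 1] @ Q[:, 1]), (P[:, 1] @ Q[:, 2])
    Szx, Szy, Szz = (P[:, 2] @ Q[:, 0]), (P[:, 2] @ Q[:, 1]), (P[:, 2] @ Q[:, 2])
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam_max = np.linalg.eigvalsh(K)[-1]
    msd = (np.sum(P**2) + np.sum(Q**2) - 2.0 * lam_max) / X.shape[0]
    return math.sqrt(max(msd, 0.0))
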