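"""Thermodynamics: heat capacity, WHAM density of states, free-energy
profiles/surfaces and melting-temperature detection.

Energies are in reduced units (contact depth 1, kB = 1), so temperature is in
units of depth/kB.  The heat capacity is the energy-fluctuation estimator
``Cv = (<E^2> - <E>^2) / T^2`` and the melting temperature is the location of
its peak.  Multi-temperature samples are combined with the weighted histogram
analysis method (WHAM) into one relative density of states, from which
observables at any temperature follow by reweighting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .analysis import MacrostateDefinition

__all__ = [
    "DensityOfStates",
    "FreeEnergyLandscape",
    "heat_capacity",
    "melting_temperature",
    "wham_fit",
    "free_energy_landscape",
    "wham_frame_weights",
    "find_basins_1d",
]


@dataclass
class DensityOfStates:
    """Relative log-density of states on an energy grid, with per-T offsets."""

    bin_edges: np.ndarray      # (B+1,)
    log_density: np.ndarray    # (B,), -inf on unoccupied bins
    temperatures: np.ndarray   # (K,)
    offsets: np.ndarray        # (K,) dimensionless free energies f_i
    n_iter: int
    converged: bool

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def reweight(self, T: float) -> tuple[float, float]:
        """Mean energy and Cv at temperature T from the density of states."""
        E = self.bin_centers
        logw = self.log_density - E / T
        logw -= logsumexp(logw[np.isfinite(logw)])
        w = np.exp(logw)
        mean = float(np.sum(w * E))
        var = float(np.sum(w * (E - mean) ** 2))
        return mean, var / T**2


@dataclass
class FreeEnergyLandscape:
    """F on a 1D or 2D grid at temperature T, gauged so min F = 0."""

    coordinates: tuple[str, ...]
    bin_edges: tuple[np.ndarray, ...]
    F: np.ndarray              # masked (nan) on empty bins
    temperature: float


def heat_capacity(samples: np.ndarray, temperature: float) -> float:
    """Fluctuation formula Cv = (<E^2> - <E>^2) / T^2."""
    E = np.asarray(samples, dtype=float)
    if E.size < 2:
        raise ValueError("heat capacity undefined for fewer than 2 samples")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return float(np.mean(E**2) - np.mean(E) ** 2) / temperature**2


def melting_temperature(temps: np.ndarray, cvs: np.ndarray) -> float:
    """Peak location of Cv(T): discrete argmax refined by a local parabola.

    Raises ``ValueError`` ("no interior peak") when the maximum sits on the
    boundary of the temperature grid, i.e. the curve is monotone over the
    sampled range.
    """
    T = np.asarray(temps, dtype=float)
    C = np.asarray(cvs, dtype=float)
    if T.size < 3:
        raise ValueError("need at least 3 temperature points")
    order = np.argsort(T)
    T, C = T[order], C[order]
    k = int(np.argmax(C))
    if k == 0 or k == T.size - 1:
        raise ValueError("no interior peak in the Cv curve")
    # quadratic through the three points around the discrete maximum
    t0, t1, t2 = T[k - 1], T[k], T[k + 1]
    c0, c1, c2 = C[k - 1], C[k], C[k + 1]
    denom = (t0 - t1) * (t0 - t2) * (t1 - t2)
    a = (t2 * (c1 - c0) + t1 * (c0 - c2) + t0 * (c2 - c1)) / denom
    b = (t2**2 * (c0 - c1) + t1**2 * (c2 - c0) + t0**2 * (c1 - c2)) / denom
    if a >= 0:  # degenerate (flat/convex) fit: keep the grid argmax
        return float(t1)
    tm = -b / (2 * a)
    return float(np.clip(tm, t0, t2))


def wham_fit(
    energy_samples: dict[float, np.ndarray] | list[tuple[float, np.ndarray]],
    bin_width: float = 2.0,
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> DensityOfStates:
    """Self-consistent WHAM over per-temperature energy histograms.

    ``energy_samples`` maps temperature -> 1D array of equilibrated energies.
    Iterates the standard pair of equations

        Omega(E) = sum_i n_i(E) / sum_i N_i exp(f_i - E/T_i)
        exp(-f_i) = sum_E Omega(E) exp(-E/T_i)

    in log space until the offsets f_i change by less than ``tol`` (sup-norm).
    Non-overlapping histograms leave the offsets drifting; the failure is
    reported via ``converged=False`` with the iteration diagnostic.
    """
    items = sorted(energy_samples.items()) if isinstance(energy_samples, dict) \
        else sorted(energy_samples)
    temps = np.array([t for t, _ in items], dtype=float)
    if np.any(temps <= 0):
        raise ValueError("temperatures must be positive")
    samples = [np.asarray(s, dtype=float) for _, s in items]
    if any(s.size == 0 for s in samples):
        raise ValueError("every temperature needs at least one sample")
    allE = np.concatenate(samples)
    lo = np.floor(allE.min() / bin_width) * bin_width - 0.5 * bin_width
    hi = np.ceil(allE.max() / bin_width) * bin_width + 0.5 * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    K, B = temps.size, centers.size
    counts = np.stack([np.histogram(s, bins=edges)[0] for s in samples]).astype(float)
    N = counts.sum(axis=1)
    occupied = counts.sum(axis=0) > 0
    log_counts_tot = np.where(occupied, np.log(np.maximum(counts.sum(axis=0), 1e-300)), -np.inf)
    beta_E = centers[None, :] / temps[:, None]         # (K, B)

    f = np.zeros(K)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # log denominator per bin: logsumexp_i [ln N_i + f_i - E_b/T_i]
        log_denom = logsumexp(np.log(N)[:, None] + f[:, None] - beta_E, axis=0)
        log_omega = np.where(occupied, log_counts_tot - log_denom, -np.inf)
        f_new = -logsumexp(log_omega[None, :] - beta_E, axis=1)
        f_new -= f_new[0]  # gauge
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        if delta < tol:
            converged = True
            break
    log_denom = logsumexp(np.log(N)[:, None] + f[:, None] - beta_E, axis=0)
    log_omega = np.where(occupied, log_counts_tot - log_denom, -np.inf)
    finite = np.isfinite(log_omega)
    log_omega = log_omega - logsumexp(log_omega[finite])
    return DensityOfStates(bin_edges=edges, log_density=log_omega,
                           temperatures=temps, offsets=f, n_iter=it,
                           converged=converged)


def wham_frame_weights(
    frame_energies: np.ndarray,
    frame_temperatures: np.ndarray,
    dos: DensityOfStates,
    T_target: float,
) -> np.ndarray:
    """Per-frame reweighting factors to temperature ``T_target``.

    ``w(E) = exp(-E/T_t) / sum_i N_i exp(f_i - E/T_i)`` with the sample counts
    and offsets taken from the WHAM fit; normalised to sum to 1.
    """
    E = np.asarray(frame_energies, dtype=float)
    src_T = np.asarray(frame_temperatures, dtype=float)
    N = np.array([np.sum(src_T == t) for t in dos.temperatures], dtype=float)
    log_denom = logsumexp(
        np.log(N)[:, None] + dos.offsets[:, None] - E[None, :] / dos.temperatures[:, None],
        axis=0,
    )
    logw = -E / T_target - log_denom
    logw -= logsumexp(logw)
    return np.exp(logw)


def free_energy_landscape(
    values: np.ndarray,
    temperature: float,
    bins,
    coordinates: tuple[str, ...] = ("E",),
    weights: np.ndarray | None = None,
) -> FreeEnergyLandscape:
    """F(x) = -T ln P(x) on a 1D or 2D grid, gauged to min 0.

    ``values`` is (n_frames,) or (n_frames, 2); ``weights`` (e.g. from
    :func:`wham_frame_weights`) reweights multi-temperature input.  Empty bins
    are masked with NaN, never interpolated.
    """
    vals = np.asarray(values, dtype=float)
    if vals.ndim == 1:
        vals = vals[:, None]
    dims = vals.shape[1]
    if dims not in (1, 2):
        raise ValueError("only 1D and 2D landscapes are supported")
    if len(coordinates) != dims:
        raise ValueError("coordinate names must match dimensionality")
    if dims == 1:
        hist, e0 = np.histogram(vals[:, 0], bins=bins, weights=weights)
        edges = (e0,)
    else:
        hist, e0, e1 = np.histogram2d(vals[:, 0], vals[:, 1], bins=bins, weights=weights)
        edges = (e0, e1)
    P = hist / hist.sum()
    with np.errstate(divide="ignore"):
        F = -temperature * np.log(P)
    F[~np.isfinite(F)] = np.nan
    F -= np.nanmin(F)
    return FreeEnergyLandscape(coordinates=tuple(coordinates), bin_edges=edges,
                               F=F, temperature=temperature)


def find_basins_1d(landscape: FreeEnergyLandscape, min_barrier: float = 0.0) -> MacrostateDefinition:
    """Basins of a 1D profile, bounded at barrier tops (watershed).

    Local minima of F separated by local maxima define the basins; each basin
    window spans from the preceding barrier top (or the profile edge) to the
    following one.  Adjacent basins whose separating barrier rises less than
    ``min_barrier`` above the shallower of the two minima are merged, which
    suppresses binning-noise dips.  Windows are named basin0, basin1, ... in
    coordinate order.
    """
    F = landscape.F
    if F.ndim != 1:
        raise ValueError("basin extraction requires a 1D profile")
    edges = landscape.bin_edges[0]
    valid = np.nonzero(np.isfinite(F))[0]
    if valid.size == 0:
        raise ValueError("empty profile")
    Fv = F[valid]
    minima = [k for k in range(Fv.size)
              if (k == 0 or Fv[k] <= Fv[k - 1]) and (k == Fv.size - 1 or Fv[k] < Fv[k + 1])]
    # merge plateau minima
    minima = [m for i, m in enumerate(minima) if i == 0 or m > minima[i - 1] + 1 or Fv[m] != Fv[minima[i - 1]]]
    if not minima:
        raise ValueError("no basin found")
    barriers = [a + int(np.argmax(Fv[a:b + 1])) for a, b in zip(minima, minima[1:])]
    # prominence filter: drop the least significant barrier until all clear min_barrier
    while barriers:
        depths = [Fv[bar] - max(Fv[m1], Fv[m2])
                  for m1, bar, m2 in zip(minima, barriers, minima[1:])]
        k = int(np.argmin(depths))
        if depths[k] >= min_barrier:
            break
        m1, m2 = minima[k], minima[k + 1]
        keep = m1 if Fv[m1] <= Fv[m2] else m2
        minima = minima[:k] + [keep] + minima[k + 2:]
        barriers = [a + int(np.argmax(Fv[a:b + 1])) for a, b in zip(minima, minima[1:])]
    bounds = [valid[0]] + [valid[k] for k in barriers] + [valid[-1] + 1]
    windows = {}
    for i in range(len(minima)):
        lo = edges[bounds[i]]
        hi = edges[bounds[i + 1]]
        windows[f"basin{i}"] = (float(lo), float(hi))
    return MacrostateDefinition(windows)
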