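"""Temperature replica exchange over DMD segments.

Replicas run independent event-driven segments at their current temperatures;
between segments, adjacent temperature pairs attempt a Metropolis swap with
acceptance ``min(1, exp[(1/T_i - 1/T_j)(E_i - E_j)])``.  Temperatures (not
configurations) are relabeled on acceptance and velocities are rescaled by
``sqrt(T_new/T_old)``.  Odd/even pairs alternate between sweeps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .engine import EngineParams, PairTables, SimState, initialize_state, run_dmd

__all__ = ["TemperatureLadder", "REResult", "attempt_swap", "run_replica_exchange"]


@dataclass
class TemperatureLadder:
    temperatures: list[float]
    exchange_interval: int = 50_000  # events between swap sweeps

    def __post_init__(self) -> None:
        T = list(self.temperatures)
        if len(T) < 2:
            raise ValueError("need at least 2 replicas")
        if any(b <= a for a, b in zip(T, T[1:])):
            raise ValueError("temperatures must be strictly increasing")
        if any(t <= 0 for t in T):
            raise ValueError("temperatures must be positive")


@dataclass
class REResult:
    temperatures: np.ndarray
    energy_by_temperature: dict[float, list[float]]
    frames_by_temperature: dict[float, list[np.ndarray]]
    swap_record: list[tuple[int, int, int, bool]]  # (sweep, slot i, slot j, accepted)
    replica_at_slot: list[list[int]]               # per sweep: replica id per T slot
    acceptance_rate: float = 0.0


def attempt_swap(E_i: float, T_i: float, E_j: float, T_j: float,
                 rng: np.random.Generator) -> bool:
    """Metropolis acceptance for exchanging temperatures T_i and T_j."""
    if T_i <= 0 or T_j <= 0:
        raise ValueError("temperatures must be positive")
    log_p = (1.0 / T_i - 1.0 / T_j) * (E_i - E_j)
    if log_p >= 0:
        return True
    return rng.random() < math.exp(log_p)


def run_replica_exchange(
    tables: PairTables,
    native_positions: np.ndarray,
    ladder: TemperatureLadder,
    n_sweeps: int,
    params: EngineParams,
    seed: int = 0,
    sample_every: int | None = None,
    collect_frames: bool = False,
    states: list[SimState] | None = None,
) -> REResult:
    """Alternate DMD segments with adjacent-pair temperature swap sweeps.

    Each sweep advances every replica by ``ladder.exchange_interval`` events
    (sampling observables every ``sample_every`` events, default one sample
    per segment), then attempts swaps on alternating odd/even adjacent pairs.
    Returns per-temperature energy samples (and frames), the swap record and
    the replica occupancy per temperature slot for diagnostics.
    """
    temps = list(ladder.temperatures)
    M = len(temps)
    rng = np.random.default_rng(seed)
    if states is None:
        states = [
            initialize_state(tables, native_positions, temps[m],
                             int(rng.integers(0, 2**31 - 1)))
            for m in range(M)
        ]
    # slot s holds temperature temps[s]; replica_of[s] = replica index in slot s
    replica_of = list(range(M))
    slot_of = list(range(M))
    energy_by_T: dict[float, list[float]] = {t: [] for t in temps}
    frames_by_T: dict[float, list[np.ndarray]] = {t: [] for t in temps}
    swap_record: list[tuple[int, int, int, bool]] = []
    occupancy: list[list[int]] = []
    se = ladder.exchange_interval if sample_every is None else sample_every
    n_acc = n_try = 0
    for sweep in range(n_sweeps):
        for s in range(M):
            r = replica_of[s]
            p = EngineParams(temperature=temps[s],
                             thermostat_rate=params.thermostat_rate,
                             seed=int(rng.integers(0, 2**31 - 1)),
                             alpha=params.alpha, lam=params.lam,
                             b0=params.b0, b1=params.b1, box=params.box)
            traj = run_dmd(states[r], ladder.exchange_interval, p, tables,
                           sample_every=se, native_positions=native_positions,
                           collect_frames=collect_frames)
            energy_by_T[temps[s]].extend(traj.energy)
            if collect_frames:
                frames_by_T[temps[s]].extend(traj.frames)
        first = sweep % 2
        for s in range(first, M - 1, 2):
            ri, rj = replica_of[s], replica_of[s + 1]
            Ei, Ej = states[ri].potential, states[rj].potential
            ok = attempt_swap(Ei, temps[s], Ej, temps[s + 1], rng)
            swap_record.append((sweep, s, s + 1, ok))
            n_try += 1
            if ok:
                n_acc += 1
                scale = math.sqrt(temps[s + 1] / temps[s])
                states[ri].velocities *= scale      # replica ri: T_s -> T_{s+1}
                states[rj].velocities /= scale      # replica rj: T_{s+1} -> T_s
                replica_of[s], replica_of[s + 1] = rj, ri
                slot_of[ri], slot_of[rj] = s + 1, s
        occupancy.append(list(replica_of))
    return REResult(
        temperatures=np.array(temps),
        energy_by_temperature=energy_by_T,
        frames_by_temperature=frames_by_T,
        swap_record=swap_record,
        replica_at_slot=occupancy,
        acceptance_rate=(n_acc / n_try) if n_try else 0.0,
    )
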