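"""Event-driven (discrete) molecular dynamics over square-well potentials.

Atoms are unit-mass hard spheres; interactions are piecewise constant:

* non-bonded pairs repel below the hard core ``sigma_ij = alpha*(r_i + r_j)``;
* native contacts additionally carry an attractive well of depth 1 (reduced
  units) extending to ``lambda*sigma_ij``;
* covalent and covalent-like bonds are infinitely high wells
  ``[0.9 L, 1.1 L]`` around the native length ``L``.

Between discontinuities atoms move ballistically; at a discontinuity the
radial component of the relative velocity is updated so that linear momentum
is always conserved and total energy is conserved exactly (well entry converts
the potential drop into radial kinetic energy; an exit attempt succeeds only
if the radial kinetic energy exceeds the well depth, otherwise it reflects).
Temperature is imposed by an Andersen-style thermostat: Poisson-scheduled
redraws of single-atom velocities from the Maxwell-Boltzmann distribution.

Reduced units throughout: mass 1, well depth 1, kB 1, lengths in Å.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .structure import AtomRecord, BondNetwork, NativeContactSet

__all__ = [
    "EngineParams",
    "SimState",
    "Trajectory",
    "PairTables",
    "build_pair_tables",
    "initialize_state",
    "run_dmd",
    "total_potential_energy",
    "write_trajectory_tsv",
    "IntegrityError",
]


class IntegrityError(RuntimeError):
    """A sampled frame violates a hard core or a bond well."""


@dataclass
class EngineParams:
    temperature: float = 1.0
    thermostat_rate: float = 0.1   # Andersen redraws per atom per reduced time; 0 = NVE
    seed: int = 0
    alpha: float = 0.80
    lam: float = 1.6
    b0: float = 0.9
    b1: float = 1.1
    box: float = 0.0               # reflecting cubic box side; 0 = unbounded

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.lam <= 1:
            raise ValueError("lam must exceed 1")
        if not (self.b0 < 1 < self.b1):
            raise ValueError("bond well must bracket the native length")


# pair codes
_NONE, _REP, _CONTACT, _BOND = -1, 0, 1, 2


@dataclass
class PairTables:
    """Dense per-pair interaction tables for the event kernel."""

    code: np.ndarray   # (N, N) int8
    din: np.ndarray    # inner discontinuity (hard core / inner bond wall), Å
    dout: np.ndarray   # outer discontinuity (well edge / outer bond wall), Å
    contact_index: np.ndarray  # (n_contacts, 2) int64, i < j

    @property
    def n_atoms(self) -> int:
        return self.code.shape[0]


def build_pair_tables(
    atoms: list[AtomRecord],
    bonds: BondNetwork,
    contacts: NativeContactSet,
    b0: float = 0.9,
    b1: float = 1.1,
) -> PairTables:
    n = len(atoms)
    rad = np.array([a.vdw_radius for a in atoms])
    code = np.full((n, n), _REP, dtype=np.int8)
    np.fill_diagonal(code, _NONE)
    sig = contacts.alpha * (rad[:, None] + rad[None, :])
    din = sig.copy()
    dout = np.zeros((n, n))
    for (i, j), s in zip(contacts.pairs, contacts.sigma):
        code[i, j] = code[j, i] = _CONTACT
        din[i, j] = din[j, i] = s
        dout[i, j] = dout[j, i] = contacts.lam * s
    for i, j, length in bonds.all_bonds():
        code[i, j] = code[j, i] = _BOND
        din[i, j] = din[j, i] = b0 * length
        dout[i, j] = dout[j, i] = b1 * length
    cidx = np.array(contacts.pairs, dtype=np.int64).reshape(-1, 2)
    return PairTables(code=code, din=din, dout=dout, contact_index=cidx)


@dataclass
class SimState:
    positions: np.ndarray   # (N, 3) Å
    velocities: np.ndarray  # (N, 3) reduced
    clock: float
    in_well: np.ndarray     # (N, N) uint8, native-contact well occupancy
    potential: float        # -(# contacts currently in well)

    def copy(self) -> "SimState":
        return SimState(self.positions.copy(), self.velocities.copy(),
                        self.clock, self.in_well.copy(), self.potential)

    def kinetic_energy(self) -> float:
        return 0.5 * float(np.sum(self.velocities ** 2))

    def total_energy(self) -> float:
        return self.potential + self.kinetic_energy()


@dataclass
class Trajectory:
    """Observables sampled every ``sample_every`` events."""

    event_index: list[int] = field(default_factory=list)
    time: list[float] = field(default_factory=list)
    energy: list[float] = field(default_factory=list)
    rg: list[float] = field(default_factory=list)
    rmsd: list[float] = field(default_factory=list)
    frames: list[np.ndarray] = field(default_factory=list)
    sample_every: int = 0
    elapsed_time: float = 0.0      # reduced time covered by this trajectory
    time_integral_U: float = 0.0   # ∫ U dt (for unbiased time averages)
    time_integral_U2: float = 0.0

    @property
    def time_average_energy(self) -> float:
        return self.time_integral_U / self.elapsed_time

    @property
    def time_variance_energy(self) -> float:
        m = self.time_average_energy
        return self.time_integral_U2 / self.elapsed_time - m * m


def write_trajectory_tsv(traj: Trajectory, path: str) -> None:
    """Columnar sample table: event index, clock, E, Rg and (if sampled) RMSD."""
    with open(path, "w") as fh:
        has_rmsd = bool(traj.rmsd)
        fh.write("event\ttime\tE\trg" + ("\trmsd" if has_rmsd else "") + "\n")
        for k in range(len(traj.event_index)):
            row = (f"{traj.event_index[k]}\t{traj.time[k]:.6f}\t"
                   f"{traj.energy[k]:.6g}\t{traj.rg[k]:.6f}")
            if has_rmsd:
                row += f"\t{traj.rmsd[k]:.6f}"
            fh.write(row + "\n")


def maxwell_velocities(n: int, temperature: float, rng: np.random.Generator) -> np.ndarray:
    """Maxwell-Boltzmann velocities at T with net momentum removed."""
    if temperature <= 0:
        return np.zeros((n, 3))
    v = rng.normal(0.0, math.sqrt(temperature), size=(n, 3))
    return v - v.mean(axis=0)


def initialize_state(
    tables: PairTables,
    positions: np.ndarray,
    temperature: float,
    seed: int,
) -> SimState:
    """Native-coordinate start with thermal velocities; refuses clashing input."""
    pos = np.asarray(positions, dtype=float).copy()
    in_well = _init_wells(tables, pos)
    check_integrity(tables, pos, in_well)
    rng = np.random.default_rng(seed)
    vel = maxwell_velocities(tables.n_atoms, temperature, rng)
    potential = -float(in_well[np.triu_indices(tables.n_atoms, 1)].sum())
    return SimState(pos, vel, 0.0, in_well, potential)


def _init_wells(tables: PairTables, pos: np.ndarray) -> np.ndarray:
    n = tables.n_atoms
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    in_well = ((tables.code == _CONTACT) & (d < tables.dout)).astype(np.uint8)
    return in_well


def check_integrity(tables: PairTables, pos: np.ndarray, in_well=None, tol: float = 1e-7) -> None:
    """Assert no hard-core overlap and every bond inside its well."""
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    iu = np.triu_indices(tables.n_atoms, 1)
    code, din, dout = tables.code[iu], tables.din[iu], tables.dout[iu]
    dd = d[iu]
    core = (code == _REP) | (code == _CONTACT)
    if np.any(dd[core] < din[core] - tol):
        raise IntegrityError("hard-core overlap detected")
    bond = code == _BOND
    if np.any(dd[bond] < din[bond] - tol) or np.any(dd[bond] > dout[bond] + tol):
        raise IntegrityError("bond outside its well")


def total_potential_energy(positions: np.ndarray, contacts: NativeContactSet) -> float:
    """E = -(number of native pairs currently inside [sigma, lambda*sigma)).

    Raises :class:`IntegrityError` on any hard-core violation among the
    native pairs (non-native pairs contribute 0 by construction).
    """
    pos = np.asarray(positions, dtype=float)
    idx = np.array(contacts.pairs, dtype=int).reshape(-1, 2)
    if idx.size == 0:
        return 0.0
    d = np.linalg.norm(pos[idx[:, 0]] - pos[idx[:, 1]], axis=1)
    if np.any(d < contacts.sigma - 1e-9):
        raise IntegrityError("pair inside hard core: infinite energy")
    return -float(np.count_nonzero(d < contacts.lam * contacts.sigma))


# --------------------------------------------------------------------------
# numba kernel
# --------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _pair_time(pos, vel, code, din, dout, in_well, i, j, clock):
    """Absolute time and kind of the next discontinuity for pair (i, j).

    kinds: 0 elastic inner (core / inner bond wall), 1 well entry,
    2 well-exit attempt, 3 outer bond wall (elastic). (-1, inf) if none.
    """
    c = code[i, j]
    if c < 0:
        return np.inf, -1
    dx0 = pos[i, 0] - pos[j, 0]
    dx1 = pos[i, 1] - pos[j, 1]
    dx2 = pos[i, 2] - pos[j, 2]
    dv0 = vel[i, 0] - vel[j, 0]
    dv1 = vel[i, 1] - vel[j, 1]
    dv2 = vel[i, 2] - vel[j, 2]
    b = dx0 * dv0 + dx1 * dv1 + dx2 * dv2
    v2 = dv0 * dv0 + dv1 * dv1 + dv2 * dv2
    if v2 <= 0.0:
        return np.inf, -1
    r2 = dx0 * dx0 + dx1 * dx1 + dx2 * dx2
    if c == _REP or (c == _CONTACT and in_well[i, j] == 0):
        # only an approach event exists
        edge = din[i, j] if c == _REP else dout[i, j]
        kind = 0 if c == _REP else 1
        if b < 0.0:
            disc = b * b - v2 * (r2 - edge * edge)
            if disc > 0.0:
                t = (-b - math.sqrt(disc)) / v2
                if t < 0.0:
                    t = 0.0
                return clock + t, kind
        return np.inf, -1
    # bonded pair, or contact currently inside its well: bounded by dout
    do = dout[i, j]
    disc_out = b * b - v2 * (r2 - do * do)
    if disc_out < 0.0:
        disc_out = 0.0
    t_out = (-b + math.sqrt(disc_out)) / v2
    if t_out < 0.0:
        t_out = 0.0
    kind_out = 2 if c == _CONTACT else 3
    if b < 0.0:
        di = din[i, j]
        disc = b * b - v2 * (r2 - di * di)
        if disc > 0.0:
            t_in = (-b - math.sqrt(disc)) / v2
            if 0.0 <= t_in < t_out:
                return clock + t_in, 0
    return clock + t_out, kind_out


@njit(cache=True, inline="always")
def _wall_time(pos, vel, x, box, clock):
    best = np.inf
    axis = -1
    for k in range(3):
        v = vel[x, k]
        if v > 0.0:
            t = (box - pos[x, k]) / v
        elif v < 0.0:
            t = -pos[x, k] / v
        else:
            continue
        if t < 0.0:
            t = 0.0
        if t < best:
            best = t
            axis = k
    return clock + best, axis


@njit(cache=True)
def _rescan_atom(pos, vel, code, din, dout, in_well, x, clock,
                 nt, npart, nkind, thermo_t, box, improve_others):
    n = pos.shape[0]
    best = thermo_t[x]
    bp = -2
    bk = 0
    if box > 0.0:
        tw, axis = _wall_time(pos, vel, x, box, clock)
        if tw < best:
            best = tw
            bp = -3
            bk = axis
    for j in range(n):
        if j == x:
            continue
        t, k = _pair_time(pos, vel, code, din, dout, in_well, x, j, clock)
        if t < best:
            best = t
            bp = j
            bk = k
        if improve_others and t < nt[j]:
            nt[j] = t
            npart[j] = x
            nkind[j] = k
    nt[x] = best
    npart[x] = bp
    nkind[x] = bk


@njit(cache=True)
def _run_kernel(pos, vel, code, din, dout, in_well, clock, potential,
                n_events, T, nu, box, seed):
    """Advance exactly ``n_events`` discontinuity events; returns
    (clock, potential, events_done, time_integral_U, time_integral_U2)."""
    np.random.seed(seed)
    n = pos.shape[0]
    nt = np.empty(n)
    npart = np.empty(n, np.int64)
    nkind = np.empty(n, np.int64)
    thermo_t = np.full(n, np.inf)
    if nu > 0.0:
        for i in range(n):
            thermo_t[i] = clock + np.random.exponential(1.0 / nu)
    for i in range(n):
        _rescan_atom(pos, vel, code, din, dout, in_well, i, clock,
                     nt, npart, nkind, thermo_t, box, False)
    sqrt_T = math.sqrt(T) if T > 0.0 else 0.0
    acc_U = 0.0
    acc_U2 = 0.0
    ev = 0
    while ev < n_events:
        a = 0
        tmin = nt[0]
        for i in range(1, n):
            if nt[i] < tmin:
                tmin = nt[i]
                a = i
        if tmin == np.inf:
            break
        dt = tmin - clock
        acc_U += potential * dt
        acc_U2 += potential * potential * dt
        for i in range(n):
            pos[i, 0] += vel[i, 0] * dt
            pos[i, 1] += vel[i, 1] * dt
            pos[i, 2] += vel[i, 2] * dt
        clock = tmin
        b = npart[a]
        kind = nkind[a]
        if b == -2:
            # Andersen thermostat: redraw one atom's velocity
            vel[a, 0] = np.random.normal() * sqrt_T
            vel[a, 1] = np.random.normal() * sqrt_T
            vel[a, 2] = np.random.normal() * sqrt_T
            thermo_t[a] = clock + np.random.exponential(1.0 / nu)
            b = -1
        elif b == -3:
            vel[a, kind] = -vel[a, kind]
            b = -1
        else:
            dx0 = pos[a, 0] - pos[b, 0]
            dx1 = pos[a, 1] - pos[b, 1]
            dx2 = pos[a, 2] - pos[b, 2]
            r = math.sqrt(dx0 * dx0 + dx1 * dx1 + dx2 * dx2)
            h0 = dx0 / r
            h1 = dx1 / r
            h2 = dx2 / r
            vr = ((vel[a, 0] - vel[b, 0]) * h0 + (vel[a, 1] - vel[b, 1]) * h1
                  + (vel[a, 2] - vel[b, 2]) * h2)
            if kind == 1:
                # well capture: potential drop of 1 becomes radial KE
                vrp = -math.sqrt(vr * vr + 4.0)
                dv = 0.5 * (vrp - vr)
                in_well[a, b] = 1
                in_well[b, a] = 1
                potential -= 1.0
            elif kind == 2 and vr * vr > 4.0:
                # successful well escape: pay the depth from radial KE
                vrp = math.sqrt(vr * vr - 4.0)
                dv = 0.5 * (vrp - vr)
                in_well[a, b] = 0
                in_well[b, a] = 0
                potential += 1.0
            else:
                # elastic: hard core, bond walls, or failed escape
                dv = -vr
            vel[a, 0] += dv * h0
            vel[a, 1] += dv * h1
            vel[a, 2] += dv * h2
            vel[b, 0] -= dv * h0
            vel[b, 1] -= dv * h1
            vel[b, 2] -= dv * h2
        _rescan_atom(pos, vel, code, din, dout, in_well, a, clock,
                     nt, npart, nkind, thermo_t, box, True)
        if b >= 0:
            _rescan_atom(pos, vel, code, din, dout, in_well, b, clock,
                         nt, npart, nkind, thermo_t, box, True)
        for j in range(n):
            if j != a and j != b and (npart[j] == a or npart[j] == b):
                _rescan_atom(pos, vel, code, din, dout, in_well, j, clock,
                             nt, npart, nkind, thermo_t, box, False)
        ev += 1
    return clock, potential, ev, acc_U, acc_U2


def run_dmd(
    state: SimState,
    n_events: int,
    params: EngineParams,
    tables: PairTables,
    sample_every: int = 50_000,
    native_positions: np.ndarray | None = None,
    collect_frames: bool = False,
    check_every: int | None = None,
) -> Trajectory:
    """Advance ``state`` in place by ``n_events`` events, sampling observables.

    ``native_positions`` enables the RMSD-to-native observable.  Integrity
    (no core overlap, bonds in wells) is verified at every sample unless
    ``check_every`` overrides the cadence.
    """
    from .analysis import radius_of_gyration, superpose_rmsd

    traj = Trajectory(sample_every=sample_every)
    if n_events <= 0:
        return traj
    rng = np.random.default_rng(params.seed)
    done = 0
    chunk = min(sample_every, n_events) if sample_every > 0 else n_events
    while done < n_events:
        step = min(chunk, n_events - done)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        clock, potential, ev, acc_U, acc_U2 = _run_kernel(
            state.positions, state.velocities, tables.code, tables.din,
            tables.dout, state.in_well, state.clock, state.potential,
            step, params.temperature, params.thermostat_rate, params.box,
            sub_seed,
        )
        traj.elapsed_time += clock - state.clock
        traj.time_integral_U += acc_U
        traj.time_integral_U2 += acc_U2
        state.clock, state.potential = clock, potential
        done += ev
        if ev < step:
            break  # no further events possible (free flight)
        if check_every is None or done % check_every == 0:
            check_integrity(tables, state.positions, state.in_well)
        traj.event_index.append(done)
        traj.time.append(state.clock)
        traj.energy.append(state.potential)
        traj.rg.append(radius_of_gyration(state.positions))
        if native_positions is not None:
            traj.rmsd.append(superpose_rmsd(state.positions, native_positions)[0])
        if collect_frames:
            traj.frames.append(state.positions.copy())
    return traj
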