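"""Event-driven dynamics core.

Beads move ballistically between discrete events:

* hard-core collisions — elastic reflection of the radial relative velocity;
* square-well crossings — entering an attractive well converts well depth to
  kinetic energy; escaping requires sufficient radial kinetic energy, else
  the pair reflects off the inner face of the well (repulsive shoulders are
  the sign-flipped case);
* bond events — bonded pairs reflect elastically at the edges of their
  infinite-well windows;
* ghost collisions — the Andersen thermostat redraws a random bead's
  velocity from the Maxwell–Boltzmann distribution at the set temperature.

Scheduling uses a per-bead earliest-event heap with collision counters for
lazy invalidation. Pair predictions use the minimum-image convention; a
periodic "horizon" rebuild bounds how far predictions may extrapolate so the
image branch cannot change under a scheduled event. Event prediction is
vectorized per bead over all partners (the systems used here are small
enough that this beats a cell-list stencil) and JIT-compiled when numba is
available.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np

from crossbeta.cgdmd.system import CGSystem, maxwell_boltzmann_velocities

try:  # optional JIT; the pure-python path is exercised when numba is absent
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


EVT_CORE = 0
EVT_WELL_IN = 1
EVT_WELL_OUT = 2
EVT_BOND_LO = 3
EVT_BOND_HI = 4

_TINY = 1e-12


class EngineError(RuntimeError):
    """Internal-consistency failure of the event loop."""


@dataclass
class Trajectory:
    """Time-ordered frames of a DMD run (positions in Å, reduced time)."""

    times: list = field(default_factory=list)
    positions: list = field(default_factory=list)
    kinetic: list = field(default_factory=list)
    potential: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def append(self, t, pos, ke, pe) -> None:
        if self.times and t <= self.times[-1]:
            raise EngineError("frame times must be strictly increasing")
        self.times.append(float(t))
        self.positions.append(np.asarray(pos))
        self.kinetic.append(float(ke))
        self.potential.append(float(pe))

    def __len__(self) -> int:
        return len(self.times)

    def total_energy(self) -> np.ndarray:
        return np.asarray(self.kinetic) + np.asarray(self.potential)

    def frames(self, topology, box_edge: float):
        """Yield fibrilmetrics Frames (NH/CO/CA/R bead views)."""
        from crossbeta.fibrilmetrics import Frame

        for t, pos in zip(self.times, self.positions):
            yield Frame(
                nh=topology.bead_positions_by_kind(pos, 0),
                co=topology.bead_positions_by_kind(pos, 2),
                ca=topology.bead_positions_by_kind(pos, 1),
                sc=topology.bead_positions_by_kind(pos, 3),
                box_edge=box_edge,
                time=t,
            )

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("times", data=np.asarray(self.times))
            fh.create_dataset("positions", data=np.stack(self.positions))
            fh.create_dataset("kinetic", data=np.asarray(self.kinetic))
            fh.create_dataset("potential", data=np.asarray(self.potential))
            for k, v in self.metadata.items():
                fh.attrs[k] = v

    @classmethod
    def load_hdf5(cls, path) -> "Trajectory":
        import h5py

        traj = cls()
        with h5py.File(path, "r") as fh:
            traj.times = list(np.asarray(fh["times"]))
            traj.positions = list(np.asarray(fh["positions"]))
            traj.kinetic = list(np.asarray(fh["kinetic"]))
            traj.potential = list(np.asarray(fh["potential"]))
            traj.metadata = dict(fh.attrs)
        return traj


@njit(cache=True)
def _predict(
    i, t_now, t_limit, pos, vel, tupd, box,
    core2, well_r2, well_eps, bond_lo2, bond_hi2, inside,
):
    """Earliest event for bead i against all partners, up to t_limit.

    Returns (t_event, partner, kind); t_event = inf when none.
    """
    n = pos.shape[0]
    best_t = np.inf
    best_j = -1
    best_kind = -1
    xi0 = pos[i, 0] + vel[i, 0] * (t_now - tupd[i])
    xi1 = pos[i, 1] + vel[i, 1] * (t_now - tupd[i])
    xi2 = pos[i, 2] + vel[i, 2] * (t_now - tupd[i])
    for j in range(n):
        if j == i:
            continue
        dtj = t_now - tupd[j]
        rx = pos[j, 0] + vel[j, 0] * dtj - xi0
        ry = pos[j, 1] + vel[j, 1] * dtj - xi1
        rz = pos[j, 2] + vel[j, 2] * dtj - xi2
        rx -= box * round(rx / box)
        ry -= box * round(ry / box)
        rz -= box * round(rz / box)
        vx = vel[j, 0] - vel[i, 0]
        vy = vel[j, 1] - vel[i, 1]
        vz = vel[j, 2] - vel[i, 2]
        rr = rx * rx + ry * ry + rz * rz
        rv = rx * vx + ry * vy + rz * vz
        vv = vx * vx + vy * vy + vz * vz
        if vv <= 0.0:
            continue
        hi2 = bond_hi2[i, j]
        if hi2 > 0.0:  # bonded pair: reflect inside [lo, hi]
            lo2 = bond_lo2[i, j]
            t_evt = np.inf
            kind = -1
            if rv < 0.0 and lo2 > 0.0:
                disc = rv * rv - vv * (rr - lo2)
                if disc > 0.0:
                    t_evt = (-rv - math.sqrt(disc)) / vv
                    kind = EVT_BOND_LO
            if kind == -1 or t_evt < 0.0:
                disc = rv * rv - vv * (rr - hi2)
                if disc < 0.0:
                    disc = 0.0
                t_o = (-rv + math.sqrt(disc)) / vv
                if rr >= hi2 and rv > 0.0:
                    t_o = 0.0  # numerical drift: bounce now
                if kind == -1 or t_o < t_evt:
                    t_evt = t_o
                    kind = EVT_BOND_HI
            if t_evt >= 0.0 and t_now + t_evt < best_t and t_now + t_evt <= t_limit:
                best_t = t_now + t_evt
                best_j = j
                best_kind = kind
            continue
        wr2 = well_r2[i, j]
        c2 = core2[i, j]
        if wr2 > 0.0 and inside[i, j]:
            t_evt = np.inf
            kind = -1
            if rv < 0.0 and c2 > 0.0:
                disc = rv * rv - vv * (rr - c2)
                if disc > 0.0:
                    t_evt = (-rv - math.sqrt(disc)) / vv
                    kind = EVT_CORE
            if kind == -1:
                disc = rv * rv - vv * (rr - wr2)
                if disc < 0.0:
                    disc = 0.0
                t_evt = (-rv + math.sqrt(disc)) / vv
                if rr >= wr2 and rv > 0.0:
                    t_evt = 0.0
                kind = EVT_WELL_OUT
            if t_evt >= 0.0 and t_now + t_evt < best_t and t_now + t_evt <= t_limit:
                best_t = t_now + t_evt
                best_j = j
                best_kind = kind
            continue
        if wr2 > 0.0:  # outside the well: capture is the first contact
            if rv < 0.0:
                disc = rv * rv - vv * (rr - wr2)
                if disc > 0.0 and rr > wr2:
                    t_evt = (-rv - math.sqrt(disc)) / vv
                    if t_evt >= 0.0 and t_now + t_evt < best_t and (
                        t_now + t_evt <= t_limit
                    ):
                        best_t = t_now + t_evt
                        best_j = j
                        best_kind = EVT_WELL_IN
            continue
        if c2 > 0.0 and rv < 0.0:
            disc = rv * rv - vv * (rr - c2)
            if disc > 0.0:
                t_evt = (-rv - math.sqrt(disc)) / vv
                if rr <= c2 and rv < 0.0:
                    t_evt = 0.0
                if t_evt >= 0.0 and t_now + t_evt < best_t and (
                    t_now + t_evt <= t_limit
                ):
                    best_t = t_now + t_evt
                    best_j = j
                    best_kind = EVT_CORE
    return best_t, best_j, best_kind


def _init_inside(system: CGSystem) -> np.ndarray:
    from crossbeta.cgdmd.system import _pair_distances_sq

    d2 = _pair_distances_sq(system.positions, system.box_edge)
    inside = (system.well_r2 > 0) & (d2 < system.well_r2)
    return np.ascontiguousarray(inside)


def run_dmd(
    system: CGSystem,
    t_end: float,
    thermostat_rate: float | None = None,
    frame_interval: float = 10.0,
    seed: int = 0,
    max_events: int | None = None,
    collect_events: bool = False,
) -> Trajectory:
    """Evolve the system by event-driven dynamics for ``t_end`` reduced time.

    ``thermostat_rate`` is the Andersen ghost-collision rate per bead per τ
    (None → the parameter set's default; 0 disables the thermostat, giving
    microcanonical dynamics whose total energy is conserved). The system is
    modified in place; frames are recorded every ``frame_interval`` plus one
    final frame at ``t_end``.
    """
    if t_end <= 0:
        raise EngineError("t_end must be positive")
    params = system.params
    rate = params.ghost_rate if thermostat_rate is None else float(thermostat_rate)
    n = system.n_beads
    rng = np.random.default_rng(seed)

    pos = np.ascontiguousarray(system.positions, dtype=np.float64)
    vel = np.ascontiguousarray(system.velocities, dtype=np.float64)
    mass = system.masses
    inv_mass = 1.0 / mass
    tupd = np.zeros(n)
    counter = np.zeros(n, dtype=np.int64)
    inside = _init_inside(system)
    box = system.box_edge
    kT = system.kT

    pe = -float((system.well_eps * inside).sum()) / 2.0  # pairs double-counted
    heap: list = []
    t_now = 0.0

    def horizon_dt() -> float:
        vmax = float(np.sqrt((vel**2).sum(axis=1)).max())
        if vmax <= 0:
            return t_end
        return box / (8.0 * vmax)

    horizon = min(t_end, horizon_dt())

    def schedule(i: int) -> None:
        t_evt, j, kind = _predict(
            i, t_now, horizon, pos, vel, tupd, box,
            system.core2, system.well_r2, system.well_eps,
            system.bond_lo2, system.bond_hi2, inside,
        )
        if np.isfinite(t_evt):
            cj = counter[j] if j >= 0 else -1
            heapq.heappush(heap, (t_evt, i, j, kind, counter[i], cj))

    def rebuild() -> None:
        heap.clear()
        for i in range(n):
            schedule(i)

    def advance(i: int, t: float) -> None:
        pos[i] += vel[i] * (t - tupd[i])
        tupd[i] = t

    rebuild()
    next_ghost = (
        t_now + rng.exponential(1.0 / (rate * n)) if rate > 0 else np.inf
    )

    traj = Trajectory(
        metadata={
            "seed": seed,
            "temperature_K": system.temperature_K,
            "box_edge": box,
            "sequence": system.topology.sequence,
            "n_peptides": system.topology.n_peptides,
            "thermostat_rate": rate,
        }
    )

    def snapshot(t: float) -> None:
        for i in range(n):
            advance(i, t)
        ke = float(0.5 * (mass * (vel**2).sum(axis=1)).sum())
        traj.append(t, pos.copy(), ke, pe)

    next_frame = frame_interval
    n_events = 0
    event_log: list = []
    ghost_log: list = []
    while True:
        t_evt, i, j, kind, ci, cj = heap[0] if heap else (np.inf, -1, -1, -1, 0, 0)
        t_next = min(t_evt, next_ghost, horizon)

        while next_frame <= min(t_next, t_end) + _TINY:
            snapshot(next_frame)
            next_frame += frame_interval
        if t_next >= t_end:
            if not traj.times or traj.times[-1] < t_end - _TINY:
                snapshot(t_end)
            break

        if t_next < t_now - 1e-9:
            raise EngineError(
                f"event-time regression: {t_next} < {t_now}"
            )

        if t_next == horizon and horizon <= min(t_evt, next_ghost):
            t_now = horizon
            horizon = min(t_end + _TINY, t_now + horizon_dt())
            rebuild()
            continue

        if next_ghost <= t_evt:
            t_now = next_ghost
            gi = int(rng.integers(n))
            advance(gi, t_now)
            vel[gi] = rng.normal(size=3) * math.sqrt(kT * inv_mass[gi])
            if collect_events:
                ghost_log.append((t_now, gi, vel[gi].copy()))
            counter[gi] += 1
            schedule(gi)
            next_ghost = t_now + rng.exponential(1.0 / (rate * n))
            continue

        heapq.heappop(heap)
        if ci != counter[i]:
            continue  # bead i has a newer schedule in the heap
        if j >= 0 and cj != counter[j]:
            schedule(i)
            continue
        t_now = t_evt
        dpe = _process_pair(
            i, j, kind, t_now, pos, vel, tupd, inv_mass, box,
            system.well_eps, inside,
        )
        if np.isnan(dpe):
            raise EngineError(f"coincident beads {i},{j} at event")
        pe += dpe
        if collect_events:
            event_log.append((t_now, (min(i, j), max(i, j))))
        counter[i] += 1
        counter[j] += 1
        schedule(i)
        schedule(j)
        n_events += 1
        if max_events is not None and n_events >= max_events:
            snapshot(max(t_now, traj.times[-1] + _TINY if traj.times else t_now))
            break

    system.positions = pos
    system.velocities = vel
    traj.metadata["n_events"] = n_events
    if collect_events:
        traj.metadata["events"] = event_log
        traj.metadata["ghosts"] = ghost_log
    return traj


@njit(cache=True)
def _process_pair(i, j, kind, t, pos, vel, tupd, inv_mass, box, well_eps, inside):
    """Apply the impulse for one pair event; returns the potential change.

    Returns NaN when the beads coincide (internal-consistency failure).
    """
    for k in range(3):
        pos[i, k] += vel[i, k] * (t - tupd[i])
        pos[j, k] += vel[j, k] * (t - tupd[j])
    tupd[i] = t
    tupd[j] = t
    rx = pos[j, 0] - pos[i, 0]
    ry = pos[j, 1] - pos[i, 1]
    rz = pos[j, 2] - pos[i, 2]
    rx -= box * round(rx / box)
    ry -= box * round(ry / box)
    rz -= box * round(rz / box)
    rr = rx * rx + ry * ry + rz * rz
    if rr <= 0.0:
        return np.nan
    rnorm = math.sqrt(rr)
    ux, uy, uz = rx / rnorm, ry / rnorm, rz / rnorm
    vr = (
        (vel[j, 0] - vel[i, 0]) * ux
        + (vel[j, 1] - vel[i, 1]) * uy
        + (vel[j, 2] - vel[i, 2]) * uz
    )
    mu = 1.0 / (inv_mass[i] + inv_mass[j])
    eps = well_eps[i, j]
    dpe = 0.0

    if kind == EVT_CORE or kind == EVT_BOND_LO or kind == EVT_BOND_HI:
        dvr = -2.0 * vr
    elif kind == EVT_WELL_IN:
        # potential drops by eps on entry (eps < 0 is a repulsive shoulder)
        disc = vr * vr + 2.0 * eps / mu
        if disc > 0.0:
            vr_new = math.copysign(math.sqrt(disc), vr)
            inside[i, j] = True
            inside[j, i] = True
            dpe = -eps
        else:  # shoulder too high: bounce off the outer face
            vr_new = -vr
        dvr = vr_new - vr
    else:  # EVT_WELL_OUT
        disc = vr * vr - 2.0 * eps / mu
        if disc > 0.0:
            vr_new = math.copysign(math.sqrt(disc), vr)
            inside[i, j] = False
            inside[j, i] = False
            dpe = eps
        else:  # not enough radial energy to escape: reflect inward
            vr_new = -vr
        dvr = vr_new - vr

    impulse = mu * dvr
    vel[j, 0] += impulse * inv_mass[j] * ux
    vel[j, 1] += impulse * inv_mass[j] * uy
    vel[j, 2] += impulse * inv_mass[j] * uz
    vel[i, 0] -= impulse * inv_mass[i] * ux
    vel[i, 1] -= impulse * inv_mass[i] * uy
    vel[i, 2] -= impulse * inv_mass[i] * uz
    return dpe
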