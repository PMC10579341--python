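"""Modified Eden growth model on a 3D cubic lattice.

The model describes a bacterial colony confined in a semi-dense gel.  Cells
occupy sites of an ``L**3`` cubic lattice (one cell per site, one site ~ one
cell volume ~ 1 um^3).  A cell with at least one empty face-neighbour can
divide at rate ``k``, placing the daughter on a uniformly chosen empty surface
site of the colony (the classic Eden growth rule).  A cell that is
sufficiently exposed -- at least ``n2_min_empty`` (default 4) of its six
face-neighbours empty -- can additionally make a rare dispersal "jump" at rate
``k_s``: its new position is drawn as a Gaussian displacement of standard
deviation ``sigma`` (lattice units) around its current site, rounded to the
nearest lattice site, redrawing while the target is occupied.  Jumped cells
seed satellite colonies; the interplay of ``k_s`` and ``sigma`` controls the
morphology (compact / satellite-forming / dispersed).

Dynamics are simulated exactly in continuous time with the Gillespie
algorithm: with ``N1`` cells that can only divide and ``N2`` cells that can
divide or jump, the total event rate is ``T = N1*k + N2*(k + k_s)``, waiting
times are ``tau = -ln(r)/T``, and a division happens with probability
``(N1 + N2)*k/T`` (otherwise a jump).

Two engines share one random-draw protocol (per event: ``r`` for the waiting
time, ``a`` for the event class, then the event-specific draws) and are
draw-for-draw equivalent:

* :func:`run` -- fast engine with incremental bookkeeping (Fenwick-tree
  sampling pools), suitable for the full 10**6-event runs;
* :func:`run_naive_oracle` -- deliberately naive reference engine that
  recomputes the population partition and the surface array from scratch at
  every iteration, used as a correctness oracle in the tests.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from . import _kernels as _K

logger = logging.getLogger(__name__)

__all__ = [
    "SimParams",
    "LatticeState",
    "PopulationPartition",
    "EventRecord",
    "EventLog",
    "Trajectory",
    "SimResult",
    "NEIGHBOR_OFFSETS",
    "GROWTH",
    "JUMP",
    "JUMP_ABORTED",
    "empty_neighbor_count",
    "classify_populations",
    "total_event_rate",
    "draw_waiting_time",
    "growth_probability",
    "select_event",
    "growth_event",
    "jump_event",
    "run",
    "run_naive_oracle",
]

#: Face-neighbour displacement vectors, in the fixed order used everywhere.
NEIGHBOR_OFFSETS = np.array(
    [[-1, 0, 0], [1, 0, 0], [0, -1, 0], [0, 1, 0], [0, 0, -1], [0, 0, 1]],
    dtype=np.int64,
)

# event-type codes used in EventLog / Trajectory
GROWTH = 0
JUMP = 1
JUMP_ABORTED = 2
EVENT_LABELS = {GROWTH: "growth", JUMP: "jump", JUMP_ABORTED: "jump_aborted"}

STATUS_COMPLETED = "completed"
STATUS_JAMMED = "jammed"
STATUS_TRUNCATED = "truncated"


def _default_boundary_margin(sigma: float) -> int:
    return max(int(math.ceil(3 * sigma)), 5)


@dataclass(frozen=True)
class SimParams:
    """Parameters of one simulation run.

    Parameters
    ----------
    k:
        Division rate (1/time). The time unit of the model is 1/k; by
        convention k = 1.
    k_s:
        Jump ("swim") rate of exposed cells (1/time).
    sigma:
        Standard deviation of the Gaussian jump displacement, in lattice
        units (= um at one cell per um^3).
    L:
        Linear lattice size (sites). 301 comfortably holds a 10**6-event run.
    max_events:
        Total budget of division + jump events.
    seed:
        Seed for ``numpy.random.default_rng``.
    boundary_margin:
        Stop the run (flagged as truncated) as soon as a cell is placed
        within this many sites of the lattice edge, so results are never
        edge-contaminated. Default ``max(ceil(3*sigma), 5)``.
    n2_min_empty:
        Minimum number of empty face-neighbours for a cell to be
        jump-capable (population N2). Default 4; the alternative reading
        "three or more" is one flag away.
    boundary_variant:
        "dedup" (uniform over distinct empty surface sites, the default) or
        "multiplicity" (surface sites weighted by the number of adjacent
        cells).
    redraw_cap:
        Maximum number of redraws of an occupied jump target before the jump
        is abandoned (state unchanged, warning logged).
    """

    k: float = 1.0
    k_s: float = 0.0
    sigma: float = 0.0
    L: int = 301
    max_events: int = 1_000_000
    seed: int = 0
    boundary_margin: Optional[int] = None
    n2_min_empty: int = 4
    boundary_variant: str = "dedup"
    redraw_cap: int = 10_000

    def __post_init__(self) -> None:
        if self.boundary_margin is None:
            object.__setattr__(
                self, "boundary_margin", _default_boundary_margin(self.sigma)
            )
        errors = self.validation_errors()
        if errors:
            raise ValueError("invalid SimParams: " + "; ".join(errors))

    def validation_errors(self) -> list[str]:
        errs = []
        if not self.k > 0:
            errs.append(f"k must be > 0 (got {self.k})")
        if self.k_s < 0:
            errs.append(f"k_s must be >= 0 (got {self.k_s})")
        if self.sigma < 0:
            errs.append(f"sigma must be >= 0 (got {self.sigma})")
        if self.k_s > 0 and self.sigma == 0:
            errs.append("sigma must be > 0 when k_s > 0")
        if self.L < 3:
            errs.append(f"L must be >= 3 (got {self.L})")
        if self.max_events < 1:
            errs.append(f"max_events must be >= 1 (got {self.max_events})")
        if self.boundary_margin is not None and self.boundary_margin < 1:
            errs.append(f"boundary_margin must be >= 1 (got {self.boundary_margin})")
        if not 2 <= self.n2_min_empty <= 6:
            errs.append(f"n2_min_empty must be in [2, 6] (got {self.n2_min_empty})")
        if self.boundary_variant not in ("dedup", "multiplicity"):
            errs.append(
                f"boundary_variant must be 'dedup' or 'multiplicity' "
                f"(got {self.boundary_variant!r})"
            )
        if self.redraw_cap < 1:
            errs.append(f"redraw_cap must be >= 1 (got {self.redraw_cap})")
        if self.seed < 0:
            errs.append(f"seed must be >= 0 (got {self.seed})")
        return errs

    @property
    def center(self) -> tuple[int, int, int]:
        c = self.L // 2
        return (c, c, c)


class LatticeState:
    """Sparse occupancy of an ``L**3`` cubic lattice plus the simulated clock.

    Storage is dual: a Python set of (x, y, z) tuples for mutation and
    membership tests, and a lazily built lexicographically sorted integer
    array for vectorised consumers. At most one cell per site.
    """

    def __init__(self, L: int, sites: Iterable = (), t: float = 0.0):
        self.L = int(L)
        self.t = float(t)
        self._set: set[tuple[int, int, int]] = set()
        for s in sites:
            s = (int(s[0]), int(s[1]), int(s[2]))
            self._check_site(s)
            self._set.add(s)
        self._array: Optional[np.ndarray] = None

    @classmethod
    def from_array(cls, L: int, sites: np.ndarray, t: float = 0.0) -> "LatticeState":
        """Build from an (n, 3) integer site array without materialising the set."""
        state = cls(L, (), t)
        arr = np.asarray(sites, dtype=np.int64).reshape(-1, 3)
        if arr.size and (arr.min() < 0 or arr.max() >= L):
            raise ValueError("site outside the lattice")
        order = np.lexsort((arr[:, 2], arr[:, 1], arr[:, 0]))
        state._array = arr[order]
        state._set = None  # type: ignore[assignment]
        return state

    def _check_site(self, site) -> None:
        if not all(0 <= c < self.L for c in site):
            raise ValueError(f"site {site} outside the [0, {self.L})^3 lattice")

    @property
    def occupied(self) -> set:
        if self._set is None:
            self._set = set(map(tuple, self._array.tolist()))
        return self._set

    @property
    def sites_array(self) -> np.ndarray:
        """Occupied sites as an (n, 3) int array, lexicographically sorted."""
        if self._array is None:
            if self._set:
                arr = np.array(sorted(self._set), dtype=np.int64)
            else:
                arr = np.empty((0, 3), dtype=np.int64)
            self._array = arr
        return self._array

    @property
    def n_cells(self) -> int:
        return len(self._set) if self._set is not None else len(self._array)

    def contains(self, site) -> bool:
        return tuple(site) in self.occupied

    def add(self, site) -> None:
        site = tuple(int(c) for c in site)
        self._check_site(site)
        if site in self.occupied:
            raise ValueError(f"site {site} already occupied")
        self.occupied.add(site)
        self._array = None

    def remove(self, site) -> None:
        site = tuple(int(c) for c in site)
        self.occupied.remove(site)
        self._array = None

    def __repr__(self) -> str:  # pragma: no cover
        return f"LatticeState(L={self.L}, n_cells={self.n_cells}, t={self.t:.4g})"


def empty_neighbor_count(state: LatticeState, site) -> int:
    """Number of the six face-neighbours of ``site`` that are empty.

    Neighbours outside the lattice count as blocked.
    """
    site = tuple(int(c) for c in site)
    state._check_site(site)
    occ = state.occupied
    L = state.L
    n = 0
    for dx, dy, dz in NEIGHBOR_OFFSETS:
        nb = (site[0] + dx, site[1] + dy, site[2] + dz)
        if 0 <= nb[0] < L and 0 <= nb[1] < L and 0 <= nb[2] < L and nb not in occ:
            n += 1
    return n


@dataclass(frozen=True)
class PopulationPartition:
    """The N1 (divide-only) and N2 (divide-or-jump) cell sets and the surface.

    ``boundary_sites`` lists the empty sites face-adjacent to the colony,
    lexicographically sorted; under the "multiplicity" variant a site appears
    once per adjacent cell.
    """

    n1_cells: frozenset
    n2_cells: frozenset
    boundary_sites: np.ndarray
    n2_min_empty: int = 4
    boundary_variant: str = "dedup"

    @property
    def n1(self) -> int:
        return len(self.n1_cells)

    @property
    def n2(self) -> int:
        return len(self.n2_cells)

    @property
    def n2_sorted(self) -> np.ndarray:
        """Jump-capable cells as a lexicographically sorted (n, 3) array."""
        if not self.n2_cells:
            return np.empty((0, 3), dtype=np.int64)
        return np.array(sorted(self.n2_cells), dtype=np.int64)


def classify_populations(
    state: LatticeState,
    n2_min_empty: int = 4,
    boundary_variant: str = "dedup",
) -> PopulationPartition:
    """Partition the colony into N1/N2 and collect the surface array.

    Cells with 1..(n2_min_empty-1) empty face-neighbours form N1, cells with
    >= n2_min_empty form N2; fully enclosed cells belong to neither. The
    surface array holds every empty in-lattice site adjacent to >= 1 cell.
    """
    if state.n_cells == 0:
        raise ValueError("cannot classify an empty lattice")
    occ = state.occupied
    L = state.L
    n1 = []
    n2 = []
    boundary: list[tuple[int, int, int]] = []
    for site in occ:
        e = 0
        for dx, dy, dz in NEIGHBOR_OFFSETS:
            nb = (site[0] + dx, site[1] + dy, site[2] + dz)
            if 0 <= nb[0] < L and 0 <= nb[1] < L and 0 <= nb[2] < L and nb not in occ:
                e += 1
                boundary.append(nb)
        if e >= n2_min_empty:
            n2.append(site)
        elif e >= 1:
            n1.append(site)
    if boundary_variant == "dedup":
        boundary = list(set(boundary))
    elif boundary_variant != "multiplicity":
        raise ValueError(f"unknown boundary_variant {boundary_variant!r}")
    if boundary:
        barr = np.array(sorted(boundary), dtype=np.int64)
    else:
        barr = np.empty((0, 3), dtype=np.int64)
    return PopulationPartition(
        n1_cells=frozenset(n1),
        n2_cells=frozenset(n2),
        boundary_sites=barr,
        n2_min_empty=n2_min_empty,
        boundary_variant=boundary_variant,
    )


def total_event_rate(partition: PopulationPartition, params: SimParams) -> float:
    """Total Gillespie rate ``T = N1*k + N2*(k + k_s)``.

    Returns 0 for a fully jammed colony (both populations empty), which
    signals termination rather than raising.
    """
    return partition.n1 * params.k + partition.n2 * (params.k + params.k_s)


def draw_waiting_time(T: float, rng: np.random.Generator) -> float:
    """Exponential waiting time ``tau = -ln(r)/T`` with ``r ~ U(0, 1)``.

    ``r = 0`` (possible at double precision) is redrawn so that tau is
    strictly positive and finite.
    """
    if not T > 0:
        raise ValueError(f"total rate must be > 0 (got {T})")
    r = rng.random()
    while r <= 0.0:
        r = rng.random()
    return -math.log(r) / T


def growth_probability(n1: int, n2: int, params: SimParams) -> float:
    """Probability that the next event is a division, ``(N1 + N2)*k/T``."""
    T = n1 * params.k + n2 * (params.k + params.k_s)
    if not T > 0:
        raise ValueError("total rate is zero; no event possible")
    return (n1 + n2) * params.k / T


def select_event(
    partition: PopulationPartition, params: SimParams, rng: np.random.Generator
) -> str:
    """Choose the next event class proportionally to its rate share.

    Division is selected when the uniform draw ``a`` satisfies
    ``a <= (N1 + N2)*k/T``, giving divisions exactly their rate share.
    """
    p_growth = growth_probability(partition.n1, partition.n2, params)
    a = rng.random()
    return "growth" if a <= p_growth else "jump"


@dataclass(frozen=True)
class EventRecord:
    """One simulated event; ``T`` (the total rate when it fired) is kept for audit."""

    event_type: str
    t: float
    tau: float
    site_to: tuple
    site_from: Optional[tuple] = None
    T: float = math.nan


def _draw_jump_displacement(rng: np.random.Generator, sigma: float) -> np.ndarray:
    """Component-wise rounded 3D Gaussian displacement (the shared protocol)."""
    return np.rint(rng.normal(0.0, sigma, 3)).astype(np.int64)


def growth_event(
    state: LatticeState,
    partition: PopulationPartition,
    rng: np.random.Generator,
    tau: float = math.nan,
    T: float = math.nan,
) -> EventRecord:
    """Add one cell at a uniformly chosen surface site (mutates ``state``)."""
    n = len(partition.boundary_sites)
    if n == 0:
        raise ValueError("no surface sites: cannot grow")
    idx = int(rng.integers(n))
    site = tuple(int(c) for c in partition.boundary_sites[idx])
    state.add(site)
    return EventRecord("growth", state.t, tau, site_to=site, site_from=None, T=T)


def jump_event(
    state: LatticeState,
    cell,
    params: SimParams,
    rng: np.random.Generator,
    tau: float = math.nan,
    T: float = math.nan,
) -> EventRecord:
    """Move ``cell`` by a rounded Gaussian displacement (mutates ``state``).

    Occupied or out-of-lattice targets (the origin site counts as occupied)
    trigger a full redraw of the three displacement components, up to
    ``params.redraw_cap`` attempts; a capped jump leaves the state unchanged
    and is recorded as ``jump_aborted``.
    """
    cell = tuple(int(c) for c in cell)
    if cell not in state.occupied:
        raise ValueError(f"jump origin {cell} is not occupied")
    if not params.sigma > 0:
        raise ValueError("sigma must be > 0 to jump")
    L = state.L
    for _ in range(params.redraw_cap):
        disp = _draw_jump_displacement(rng, params.sigma)
        target = (cell[0] + int(disp[0]), cell[1] + int(disp[1]), cell[2] + int(disp[2]))
        if not (0 <= target[0] < L and 0 <= target[1] < L and 0 <= target[2] < L):
            continue
        if target in state.occupied:  # includes the origin itself
            continue
        state.remove(cell)
        state.add(target)
        return EventRecord("jump", state.t, tau, site_to=target, site_from=cell, T=T)
    logger.warning(
        "jump from %s abandoned after %d occupied draws (sigma=%g)",
        cell,
        params.redraw_cap,
        params.sigma,
    )
    return EventRecord("jump_aborted", state.t, tau, site_to=cell, site_from=cell, T=T)


@dataclass
class EventLog:
    """Per-event arrays: type code, clock, waiting time, total rate, sites.

    ``site_from`` rows are (-1, -1, -1) for divisions.
    """

    event_type: np.ndarray
    t: np.ndarray
    tau: np.ndarray
    T: np.ndarray
    site_from: np.ndarray
    site_to: np.ndarray

    def __len__(self) -> int:
        return len(self.event_type)

    @property
    def labels(self) -> list[str]:
        return [EVENT_LABELS[int(c)] for c in self.event_type]

    def equals(self, other: "EventLog") -> bool:
        return (
            np.array_equal(self.event_type, other.event_type)
            and np.allclose(self.t, other.t, rtol=0, atol=0)
            and np.allclose(self.tau, other.tau, rtol=0, atol=0)
            and np.array_equal(self.site_from, other.site_from)
            and np.array_equal(self.site_to, other.site_to)
        )

    def to_dataframe(self):
        import pandas as pd

        n = len(self)
        df = pd.DataFrame(
            {
                "event_index": np.arange(n),
                "t": self.t,
                "tau": self.tau,
                "event_type": self.labels,
                "from_x": self.site_from[:, 0].astype(object),
                "from_y": self.site_from[:, 1].astype(object),
                "from_z": self.site_from[:, 2].astype(object),
                "to_x": self.site_to[:, 0],
                "to_y": self.site_to[:, 1],
                "to_z": self.site_to[:, 2],
            }
        )
        growth_rows = self.event_type == GROWTH
        for col in ("from_x", "from_y", "from_z"):
            df.loc[growth_rows, col] = None
        return df

    @classmethod
    def from_records(cls, records: list[EventRecord]) -> "EventLog":
        n = len(records)
        log = cls(
            event_type=np.empty(n, dtype=np.int8),
            t=np.empty(n, dtype=np.float64),
            tau=np.empty(n, dtype=np.float64),
            T=np.empty(n, dtype=np.float64),
            site_from=np.full((n, 3), -1, dtype=np.int32),
            site_to=np.empty((n, 3), dtype=np.int32),
        )
        code = {v: k for k, v in EVENT_LABELS.items()}
        for i, rec in enumerate(records):
            log.event_type[i] = code[rec.event_type]
            log.t[i] = rec.t
            log.tau[i] = rec.tau
            log.T[i] = rec.T
            if rec.site_from is not None:
                log.site_from[i] = rec.site_from
            log.site_to[i] = rec.site_to
        return log


@dataclass
class Trajectory:
    """Population-vs-time curve: event times, cell counts after each event."""

    times: np.ndarray
    populations: np.ndarray
    event_types: np.ndarray

    def __len__(self) -> int:
        return len(self.times)

    @classmethod
    def from_event_log(cls, log: EventLog, n0: int = 1) -> "Trajectory":
        pops = n0 + np.cumsum(log.event_type == GROWTH)
        return cls(times=log.t.copy(), populations=pops, event_types=log.event_type.copy())


@dataclass
class SimResult:
    """Outcome of one run: final state, trajectory, full event log, status."""

    params: SimParams
    state: LatticeState
    trajectory: Trajectory
    events: EventLog
    status: str
    wall_clock: float
    #: (n1, n2, total surface weight) at the end of the run, for audit.
    final_partition_counts: Optional[tuple] = None

    @property
    def n_cells(self) -> int:
        return self.state.n_cells

    def equivalent_sphere_diameter(self) -> float:
        """Diameter (um) of the sphere with the colony's volume at 1 um^3/site."""
        return (6.0 * self.n_cells / math.pi) ** (1.0 / 3.0)


def _too_close_to_edge(site, L: int, margin: int) -> bool:
    return (
        site[0] < margin
        or site[0] >= L - margin
        or site[1] < margin
        or site[1] >= L - margin
        or site[2] < margin
        or site[2] >= L - margin
    )


def run(params: SimParams, rng: Optional[np.random.Generator] = None) -> SimResult:
    """Simulate the modified Eden model with incremental bookkeeping.

    Starts from a single cell at the lattice centre and iterates
    classify -> total rate -> waiting time -> event selection -> event until
    ``max_events`` events have fired, the colony jams (T = 0), or a cell is
    placed within ``boundary_margin`` sites of the lattice edge (clean early
    stop, result flagged as truncated).  Identical (params, seed) pairs
    reproduce identical logs bit-for-bit, and match
    :func:`run_naive_oracle` draw-for-draw.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    t_start = time.perf_counter()
    L = params.L
    M = L * L * L
    thr = params.n2_min_empty
    weighted = params.boundary_variant == "multiplicity"
    occ = np.zeros(M, dtype=np.uint8)
    adj = np.zeros(M, dtype=np.int8)
    fen_b = np.zeros(M + 1, dtype=np.int32)
    fen_n2 = np.zeros(M + 1, dtype=np.int32)

    cx, cy, cz = params.center
    center = (cx * L + cy) * L + cz
    n1, n2, btot = _K.occupy(occ, adj, fen_b, fen_n2, center, L, thr, weighted)
    n_cells = 1
    t = 0.0

    max_events = params.max_events
    ev_type = np.empty(max_events, dtype=np.int8)
    ev_t = np.empty(max_events, dtype=np.float64)
    ev_tau = np.empty(max_events, dtype=np.float64)
    ev_T = np.empty(max_events, dtype=np.float64)
    ev_from = np.full((max_events, 3), -1, dtype=np.int32)
    ev_to = np.empty((max_events, 3), dtype=np.int32)

    k = params.k
    ks = params.k_s
    sigma = params.sigma
    margin = params.boundary_margin
    redraw_cap = params.redraw_cap
    sxy = L * L

    status = STATUS_COMPLETED
    n_events = 0
    rng_random = rng.random
    rng_integers = rng.integers
    log_fn = math.log
    while n_events < max_events:
        n_active = n1 + n2
        if n_active == 0:
            status = STATUS_JAMMED
            break
        T = n1 * k + n2 * (k + ks)
        r = rng_random()
        while r <= 0.0:
            r = rng_random()
        tau = -log_fn(r) / T
        t += tau
        a = rng_random()
        if a <= n_active * k / T:
            # division: uniform over the surface pool
            kk = int(rng_integers(btot))
            s = _K.fen_select(fen_b, kk)
            d1, d2, db = _K.occupy(occ, adj, fen_b, fen_n2, s, L, thr, weighted)
            n1 += d1
            n2 += d2
            btot += db
            n_cells += 1
            x = s // sxy
            rr = s - x * sxy
            y = rr // L
            z = rr - y * L
            ev_type[n_events] = GROWTH
            ev_t[n_events] = t
            ev_tau[n_events] = tau
            ev_T[n_events] = T
            ev_to[n_events, 0] = x
            ev_to[n_events, 1] = y
            ev_to[n_events, 2] = z
            n_events += 1
        else:
            # jump: uniform over N2, rounded-Gaussian target, redraw on occupied
            kk = int(rng_integers(n2))
            c = _K.fen_select(fen_n2, kk)
            x = c // sxy
            rr = c - x * sxy
            y = rr // L
            z = rr - y * L
            found = False
            for _ in range(redraw_cap):
                disp = np.rint(rng.normal(0.0, sigma, 3))
                tx = x + int(disp[0])
                ty = y + int(disp[1])
                tz = z + int(disp[2])
                if not (0 <= tx < L and 0 <= ty < L and 0 <= tz < L):
                    continue
                ti = (tx * L + ty) * L + tz
                if occ[ti]:
                    continue
                found = True
                break
            ev_t[n_events] = t
            ev_tau[n_events] = tau
            ev_T[n_events] = T
            ev_from[n_events, 0] = x
            ev_from[n_events, 1] = y
            ev_from[n_events, 2] = z
            if found:
                d1, d2, db = _K.vacate(occ, adj, fen_b, fen_n2, c, L, thr, weighted)
                n1 += d1
                n2 += d2
                btot += db
                d1, d2, db = _K.occupy(occ, adj, fen_b, fen_n2, ti, L, thr, weighted)
                n1 += d1
                n2 += d2
                btot += db
                ev_type[n_events] = JUMP
                ev_to[n_events, 0] = tx
                ev_to[n_events, 1] = ty
                ev_to[n_events, 2] = tz
                n_events += 1
                s_new = (tx, ty, tz)
            else:
                logger.warning(
                    "jump from (%d, %d, %d) abandoned after %d occupied draws",
                    x,
                    y,
                    z,
                    redraw_cap,
                )
                ev_type[n_events] = JUMP_ABORTED
                ev_to[n_events, 0] = x
                ev_to[n_events, 1] = y
                ev_to[n_events, 2] = z
                n_events += 1
                continue
            if _too_close_to_edge(s_new, L, margin):
                status = STATUS_TRUNCATED
                break
            continue
        # check the site just grown
        if _too_close_to_edge((ev_to[n_events - 1]), L, margin):
            status = STATUS_TRUNCATED
            break

    log = EventLog(
        event_type=ev_type[:n_events].copy(),
        t=ev_t[:n_events].copy(),
        tau=ev_tau[:n_events].copy(),
        T=ev_T[:n_events].copy(),
        site_from=ev_from[:n_events].copy(),
        site_to=ev_to[:n_events].copy(),
    )
    flat = np.flatnonzero(occ)
    sites = np.empty((flat.size, 3), dtype=np.int64)
    sites[:, 0] = flat // sxy
    rem = flat - sites[:, 0] * sxy
    sites[:, 1] = rem // L
    sites[:, 2] = rem - sites[:, 1] * L
    state = LatticeState.from_array(L, sites, t=t)
    traj = Trajectory.from_event_log(log)
    return SimResult(
        params=params,
        state=state,
        trajectory=traj,
        events=log,
        status=status,
        wall_clock=time.perf_counter() - t_start,
        final_partition_counts=(n1, n2, btot),
    )


def run_naive_oracle(
    params: SimParams, rng: Optional[np.random.Generator] = None
) -> SimResult:
    """Reference engine: recompute partition and surface from scratch each event.

    Intended for small event budgets (<= 10**4). Consumes the random stream in
    exactly the same order as :func:`run`, so the two produce identical event
    logs for identical (params, seed).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    t_start = time.perf_counter()
    state = LatticeState(params.L, [params.center], t=0.0)
    records: list[EventRecord] = []
    status = STATUS_COMPLETED
    while len(records) < params.max_events:
        partition = classify_populations(
            state, params.n2_min_empty, params.boundary_variant
        )
        T = total_event_rate(partition, params)
        if not T > 0:
            status = STATUS_JAMMED
            break
        tau = draw_waiting_time(T, rng)
        state.t += tau
        ev = select_event(partition, params, rng)
        if ev == "growth":
            rec = growth_event(state, partition, rng, tau=tau, T=T)
        else:
            n2s = partition.n2_sorted
            cell = tuple(int(c) for c in n2s[int(rng.integers(len(n2s)))])
            rec = jump_event(state, cell, params, rng, tau=tau, T=T)
        records.append(rec)
        if rec.event_type != "jump_aborted" and _too_close_to_edge(
            rec.site_to, params.L, params.boundary_margin
        ):
            status = STATUS_TRUNCATED
            break
    log = EventLog.from_records(records)
    final_partition = classify_populations(
        state, params.n2_min_empty, params.boundary_variant
    )
    if params.boundary_variant == "multiplicity":
        bweight = len(final_partition.boundary_sites)
    else:
        bweight = len(final_partition.boundary_sites)
    return SimResult(
        params=params,
        state=state,
        trajectory=Trajectory.from_event_log(log),
        events=log,
        status=status,
        wall_clock=time.perf_counter() - t_start,
        final_partition_counts=(final_partition.n1, final_partition.n2, bweight),
    )
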