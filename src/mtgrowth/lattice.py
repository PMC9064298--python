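"""Reference implementation of the protofilament lattice and its event rules.

This module holds the readable, event-by-event implementation of the kinetic
Monte Carlo model: the lattice state, the enumeration of all possible
reactions with their rates, and a single-step direct-method sampler.  Long
simulations use the compiled kernel in :mod:`mtgrowth.kernel`, which
implements exactly the same event rules; this module is the ground truth the
kernel is tested against and the surface for small, inspectable systems.

Lattice conventions
-------------------
* Each protofilament is a contiguous stack of dimers indexed from 0 (seed
  end) upward; ``heights[p]`` is the number of dimers in protofilament ``p``.
* The bottom ``seed_len`` layers are an immutable template (a stand-in for a
  stabilized seed): they never dissociate and never hydrolyze.
* Nucleotide state is per-dimer: GTP (0) or GDP (1).  The nucleotide acts in
  trans: the interface between dimers ``i-1`` and ``i`` takes the nucleotide
  of the lower dimer ``i-1``, and the interface a terminal dimer presents to
  incoming tubulin takes the terminal dimer's own nucleotide.
* Lateral neighbours of ``(p, i)`` are ``(p-1, i)`` and ``(p+1, i)`` with
  periodic wrap; across the seam (between the last protofilament and
  protofilament 0) the dimer index is staggered by ``seam_offset``.
* Hydrolysis (GTP -> GDP) only targets non-terminal, non-seed dimers: the
  GTPase requires a longitudinal interface formed above the nucleotide.
"""
from __future__ import annotations

import dataclasses
import math
from typing import List, Optional, Tuple

import numpy as np

from .params import ModelParams

GTP = 0
GDP = 1

ASSOCIATE = 0
DISSOCIATE = 1
HYDROLYZE = 2

_EVENT_NAMES = {ASSOCIATE: "associate", DISSOCIATE: "dissociate", HYDROLYZE: "hydrolyze"}


class FrozenSystemError(RuntimeError):
    """No reaction is possible (e.g. a bare immutable seed at zero tubulin)."""


@dataclasses.dataclass
class LatticeState:
    """13-protofilament microtubule end: contiguous dimer stacks + nucleotides."""

    heights: np.ndarray          # (n_pf,) int64, dimers per protofilament incl. seed
    nuc: np.ndarray              # (n_pf, capacity) uint8, GTP/GDP per dimer
    seed_len: int
    sim_time: float = 0.0

    @property
    def n_pf(self) -> int:
        return self.heights.shape[0]

    def copy(self) -> "LatticeState":
        return LatticeState(self.heights.copy(), self.nuc.copy(), self.seed_len,
                            self.sim_time)

    def total_subunits(self, include_seed: bool = False) -> int:
        n = int(self.heights.sum())
        return n if include_seed else n - self.n_pf * self.seed_len

    def mean_length(self, dimer_length: float = 8.2) -> float:
        """Mean length above the seed, in nm."""
        return self.total_subunits() / self.n_pf * dimer_length

    def pf_stack(self, p: int) -> np.ndarray:
        return self.nuc[p, : self.heights[p]]


@dataclasses.dataclass(frozen=True)
class Event:
    kind: int          # ASSOCIATE / DISSOCIATE / HYDROLYZE
    pf: int
    index: int         # dimer index acted on (landing index for association)
    rate: float        # s^-1

    @property
    def name(self) -> str:
        return _EVENT_NAMES[self.kind]


@dataclasses.dataclass
class EventList:
    events: List[Event]

    @property
    def total_rate(self) -> float:
        return float(sum(e.rate for e in self.events))

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)


def init_state(params: ModelParams, seed_layers: int, capacity: Optional[int] = None,
               all_gdp: bool = False, extra_layers: int = 0) -> LatticeState:
    """Construct a blunt starting lattice.

    Parameters
    ----------
    seed_layers
        Immutable template layers per protofilament (>= 1).
    capacity
        Preallocated dimers per protofilament; grows automatically if omitted.
    all_gdp
        If true, ``extra_layers`` GDP dimers are stacked above the seed —
        the initial condition for depolymerization (shrinkage) runs.
    extra_layers
        Mutable layers added above the seed at construction.
    """
    if seed_layers < 1:
        raise ValueError("seed_layers must be >= 1")
    if extra_layers < 0:
        raise ValueError("extra_layers must be >= 0")
    h0 = seed_layers + extra_layers
    if capacity is None:
        capacity = h0 + 64
    if capacity < h0:
        raise ValueError("capacity smaller than the initial height")
    heights = np.full(params.n_pf, h0, dtype=np.int64)
    nuc = np.zeros((params.n_pf, capacity), dtype=np.uint8)
    if all_gdp and extra_layers > 0:
        nuc[:, seed_layers:h0] = GDP
    return LatticeState(heights=heights, nuc=nuc, seed_len=seed_layers)


def _lateral_index(p: int, q: int, i: int, n_pf: int, seam_offset: int) -> int:
    """Dimer index in protofilament ``q`` laterally adjacent to ``(p, i)``."""
    if p == n_pf - 1 and q == 0:
        return i - seam_offset
    if p == 0 and q == n_pf - 1:
        return i + seam_offset
    return i


def lateral_neighbor_count(state: LatticeState, p: int, i: int,
                           seam_offset: int) -> int:
    """Number of occupied lateral neighbour sites of dimer position ``(p, i)``."""
    n_pf = state.n_pf
    n = 0
    for q in ((p - 1) % n_pf, (p + 1) % n_pf):
        j = _lateral_index(p, q, i, n_pf, seam_offset)
        if 0 <= j < state.heights[q]:
            n += 1
    return n


def _site_kon(params: ModelParams, n_lat: int) -> float:
    """On-rate constant for a site with ``n_lat`` lateral contacts."""
    if not params.site_dependent_kon:
        return params.k_on
    if n_lat == 0:
        return params.k_on * params.kon_ratio_long_corner
    if n_lat == 1:
        return params.k_on
    return params.k_on / params.kon_ratio_corner_bucket


def site_affinity(state: LatticeState, pf: int, params: ModelParams) -> float:
    """Dissociation constant (uM) of the terminal dimer of protofilament ``pf``.

    Energy-additive composition: ``K_D_long_eff * (K_D_corner/K_D_long)**n_lat``
    where the longitudinal term is weakened by ``gdp_factor_X`` when the
    interface below the terminal dimer is GDP.
    """
    h = int(state.heights[pf])
    if h <= state.seed_len:
        raise ValueError("protofilament has no dimers above the seed")
    i = h - 1
    below_gdp = i >= 1 and state.nuc[pf, i - 1] == GDP
    kd_long = params.K_D_long * (params.gdp_factor_X if below_gdp else 1.0)
    n_lat = lateral_neighbor_count(state, pf, i, params.seam_offset)
    return kd_long * params.lateral_ratio ** n_lat


def terminal_gdp_count(state: LatticeState) -> int:
    """Protofilaments whose exposed terminal interface is GDP.

    The interface presented to incoming tubulin carries the terminal dimer's
    own nucleotide; the immutable seed presents GTP.
    """
    n = 0
    for p in range(state.n_pf):
        h = int(state.heights[p])
        if h > state.seed_len and state.nuc[p, h - 1] == GDP:
            n += 1
    return n


def enumerate_events(state: LatticeState, params: ModelParams) -> EventList:
    """All currently possible reactions with their rates.

    One association per protofilament (atop the terminal dimer, incoming
    dimers are always GTP), at most one dissociation per protofilament
    (terminal dimer only, never the seed), and one hydrolysis event per
    non-terminal, non-seed GTP dimer.
    """
    events: List[Event] = []
    for p in range(state.n_pf):
        h = int(state.heights[p])
        # association at landing index h
        if params.tubulin_conc > 0:
            n_lat = lateral_neighbor_count(state, p, h, params.seam_offset)
            rate = _site_kon(params, n_lat) * params.tubulin_conc
            events.append(Event(ASSOCIATE, p, h, rate))
        # dissociation of the terminal dimer
        if h > state.seed_len:
            n_lat = lateral_neighbor_count(state, p, h - 1, params.seam_offset)
            kd = site_affinity(state, p, params)
            events.append(Event(DISSOCIATE, p, h - 1, _site_kon(params, n_lat) * kd))
        # hydrolysis of buried GTP dimers
        if params.k_GTPase > 0:
            for i in range(state.seed_len, h - 1):
                if state.nuc[p, i] == GTP:
                    events.append(Event(HYDROLYZE, p, i, params.k_GTPase))
    return EventList(events)


def _grow_capacity(state: LatticeState) -> None:
    cap = state.nuc.shape[1]
    nuc = np.zeros((state.n_pf, cap * 2), dtype=np.uint8)
    nuc[:, :cap] = state.nuc
    state.nuc = nuc


def apply_event(state: LatticeState, event: Event) -> None:
    """Mutate the state by one reaction."""
    p, i = event.pf, event.index
    if event.kind == ASSOCIATE:
        if state.heights[p] >= state.nuc.shape[1]:
            _grow_capacity(state)
        state.nuc[p, state.heights[p]] = GTP
        state.heights[p] += 1
    elif event.kind == DISSOCIATE:
        state.heights[p] -= 1
    else:  # HYDROLYZE
        state.nuc[p, i] = GDP


def advance(state: LatticeState, params: ModelParams,
            rng: np.random.Generator) -> Tuple[Event, float]:
    """Apply one stochastically chosen reaction (Gillespie direct method).

    Event ``i`` is chosen with probability ``rate_i / total`` and the elapsed
    time is exponential with mean ``1 / total`` — the same statistical law as
    racing independent exponential execution times and taking the fastest.
    """
    elist = enumerate_events(state, params)
    total = elist.total_rate
    if total <= 0 or len(elist) == 0:
        raise FrozenSystemError("no possible events: system is frozen")
    dt = rng.exponential(1.0 / total)
    u = rng.random() * total
    acc = 0.0
    chosen = elist.events[-1]
    for e in elist.events:
        acc += e.rate
        if u < acc:
            chosen = e
            break
    apply_event(state, chosen)
    state.sim_time += dt
    return chosen, dt
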