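"""Exact continuous-time stochastic simulation (Gillespie algorithm).

Five event classes act on the population:

1. phenotype switching, vegetative -> competent at per-cell rate ``k_in``
   and back at ``k_out`` (memory-less);
2. replication at per-cell rate ``(ones/L) * (1 - N/K)`` for vegetative
   cells, ``beta`` times that for competent cells, floored at zero above
   carrying capacity;
3. mutation, applied to the daughter genome at replication: every "one"
   flips with probability ``mu_d`` and every "zero" with ``mu_b``,
   independently across loci;
4. death at per-cell rate ``delta`` (``beta * delta`` for competent cells);
5. recombination: each competent cell, at rate ``gamma``, replaces the
   allele at one uniformly chosen locus by the allele carried at that locus
   by a uniformly chosen living cell (or by a "zero" with probability
   ``pool_lambda`` when the extracellular pool is contaminated).  The
   exchange is non-reciprocal: the displaced allele is discarded.

Waiting times are exponential in the grand total rate; event classes are
chosen proportionally to their aggregate rates and target cells by their
per-cell rates (rejection sampling inside a phenotype sector).  With a fixed
seed the event sequence is bit-reproducible.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .core import Phenotype, Population, SimulationParams

__all__ = [
    "EventType",
    "EventRatesSnapshot",
    "RunResult",
    "GillespieEngine",
    "compute_rates",
    "mutate_genome",
    "ABSORBED",
]

_VEG = int(Phenotype.VEGETATIVE)
_COMP = int(Phenotype.COMPETENT)

#: Sentinel returned by :meth:`GillespieEngine.step` when every rate is zero
#: (extinct or frozen population).
ABSORBED = "absorbed"

# How often the engine re-derives its floating-point aggregate rates from
# scratch to keep incremental round-off in check.
_RESYNC_EVERY = 1 << 16

_EV_BIRTH = 0
_EV_DEATH = 1
_EV_SWITCH_IN = 2
_EV_SWITCH_OUT = 3
_EV_RECOMBINATION = 4


class EventType(enum.IntEnum):
    BIRTH = 0
    DEATH = 1
    SWITCH_IN = 2
    SWITCH_OUT = 3
    RECOMBINATION = 4


@dataclass(frozen=True)
class EventRatesSnapshot:
    birth_total: float
    death_total: float
    switch_in_total: float
    switch_out_total: float
    recomb_total: float

    @property
    def grand_total(self) -> float:
        return (self.birth_total + self.death_total + self.switch_in_total
                + self.switch_out_total + self.recomb_total)


def compute_rates(pop: Population, params: SimulationParams) -> EventRatesSnapshot:
    """Aggregate event-class rates, recomputed honestly from the arrays.

    This is the pure reference the engine's incremental bookkeeping is
    checked against; it is O(N) and not used in the hot loop.
    """
    veg = pop.sector[_VEG]
    comp = pop.sector[_COMP]
    n_v, n_c = len(veg), len(comp)
    N = n_v + n_c
    crowd = max(0.0, 1.0 - N / params.K)
    s_v = float(pop.ones[veg].sum()) if veg else 0.0
    s_c = float(pop.ones[comp].sum()) if comp else 0.0
    birth = crowd * (s_v + params.beta * s_c) / params.L
    death = params.delta * (n_v + params.beta * n_c)
    s_in = float(pop.kin[veg].sum()) if veg else 0.0
    s_out = float(pop.kout[comp].sum()) if comp else 0.0
    recomb = params.gamma * n_c
    return EventRatesSnapshot(birth, death, s_in, s_out, recomb)


def mutate_genome(alleles: np.ndarray, params: SimulationParams,
                  rng: np.random.Generator) -> np.ndarray:
    """Return a mutated copy: each one flips w.p. ``mu_d``, each zero w.p. ``mu_b``.

    Any number of loci may flip in a single call (multiple simultaneous
    mutations per replication are allowed).
    """
    alleles = np.asarray(alleles, dtype=np.uint8)
    if params.mu_d == 0.0 and params.mu_b == 0.0:
        return alleles.copy()
    u = rng.random(alleles.shape[0])
    flip = u < np.where(alleles == 1, params.mu_d, params.mu_b)
    return alleles ^ flip


@dataclass
class RunResult:
    termination: str
    trajectory: "np.recarray"
    crossings: dict
    event_counts: np.ndarray
    time_avg_N: float
    time_avg_pc: float
    time_avg_mean_ones: float
    elapsed: float
    generations: float
    truncated: bool = False

    @property
    def births(self) -> int:
        return int(self.event_counts[int(EventType.BIRTH)])


_TRAJ_DTYPE = np.dtype([
    ("t", np.float64), ("N", np.int64), ("N_competent", np.int64),
    ("mean_ones", np.float64),
    ("births", np.int64), ("deaths", np.int64),
    ("switch_in", np.int64), ("switch_out", np.int64),
    ("recombinations", np.int64),
])


class _UniformBuffer:
    """Block-buffered uniforms in [0, 1): far cheaper than per-call draws."""

    __slots__ = ("rng", "buf", "i", "n")

    def __init__(self, rng: np.random.Generator, block: int = 8192) -> None:
        self.rng = rng
        self.n = block
        self.buf = rng.random(block)
        self.i = 0

    def next(self) -> float:
        i = self.i
        if i == self.n:
            self.buf = self.rng.random(self.n)
            i = 0
        self.i = i + 1
        return self.buf[i]


class GillespieEngine:
    """Event-driven simulation of one population.

    Parameters
    ----------
    pop
        The population to evolve (mutated in place).
    params
        Model parameters.  If omitted, ``pop.params`` is used.
    rng
        A ``numpy.random.Generator``; if omitted one is created from
        ``params.seed``.
    debug
        When true, every event is followed by a full cache consistency check
        (slow; for tests).
    """

    def __init__(self, pop: Population, params: SimulationParams | None = None,
                 rng: np.random.Generator | None = None, debug: bool = False) -> None:
        self.pop = pop
        self.params = params if params is not None else pop.params
        self.rng = rng if rng is not None else np.random.default_rng(self.params.seed)
        self.debug = debug
        self._u = _UniformBuffer(self.rng)
        self.event_counts = [0] * len(EventType)
        self._events_since_resync = 0
        # time integrals for stationary averages
        self.tint = 0.0
        self.tint_N = 0.0
        self.tint_comp = 0.0
        self.tint_ones = 0.0
        self._mutating = self.params.mu_d > 0.0 or self.params.mu_b > 0.0

    # -- rates ------------------------------------------------------------

    def rates(self) -> EventRatesSnapshot:
        """Current aggregate rates from the population's incremental caches."""
        pop, p = self.pop, self.params
        n_v = len(pop.sector[_VEG])
        n_c = len(pop.sector[_COMP])
        crowd = 1.0 - (n_v + n_c) / p.K
        if crowd < 0.0:
            crowd = 0.0
        birth = crowd * (pop.S_ones[0] + p.beta * pop.S_ones[1]) / p.L
        death = p.delta * (n_v + p.beta * n_c)
        return EventRatesSnapshot(birth, death, pop.S_kin, pop.S_kout,
                                  p.gamma * n_c)

    # -- single event -----------------------------------------------------

    def step(self):
        """Apply exactly one event.

        Returns ``(event, dt)`` — the event class as an ``EventType``-valued
        integer and the exponential waiting time — or ``ABSORBED`` when every
        rate is zero.
        """
        pop, p = self.pop, self.params
        sector = pop.sector
        n_v = len(sector[_VEG])
        n_c = len(sector[_COMP])
        N = n_v + n_c
        if N == 0:
            return ABSORBED
        crowd = 1.0 - N / p.K
        if crowd < 0.0:
            crowd = 0.0
        s_v = pop.S_ones[0]
        s_c = pop.S_ones[1]
        beta = p.beta
        r_birth = crowd * (s_v + beta * s_c) / p.L
        r_death = p.delta * (n_v + beta * n_c)
        r_in = pop.S_kin
        r_out = pop.S_kout
        r_rec = p.gamma * n_c
        total = r_birth + r_death + r_in + r_out + r_rec
        if total <= 0.0:
            return ABSORBED
        nxt = self._u.next
        dt = -math.log(1.0 - nxt()) / total
        # accumulate time averages over the holding interval
        self.tint += dt
        self.tint_N += N * dt
        self.tint_comp += n_c * dt
        self.tint_ones += ((s_v + s_c) / N) * dt
        pop.t += dt

        pick = nxt() * total
        if pick < r_birth:
            ev = self._do_birth()
        elif pick < r_birth + r_death:
            ev = self._do_death()
        elif pick < r_birth + r_death + r_in:
            ev = self._do_switch_in()
        elif pick < total - r_rec:
            ev = self._do_switch_out()
        else:
            ev = self._do_recombination()
        self.event_counts[ev] += 1

        self._events_since_resync += 1
        if self._events_since_resync >= _RESYNC_EVERY:
            self._events_since_resync = 0
            pop.resync_rate_caches()
        if self.debug:
            pop.check_consistency()
            ref = compute_rates(pop, p)
            now = self.rates()
            assert math.isclose(now.grand_total, ref.grand_total,
                                rel_tol=1e-9, abs_tol=1e-12)
        return ev, dt

    # -- event implementations -------------------------------------------

    def _pick_uniform(self, sector: list) -> int:
        return sector[int(self._u.next() * len(sector))]

    def _pick_by_ones(self, sector: list) -> int:
        """Cell weighted by its ones count (rejection, envelope L)."""
        L = self.params.L
        ones = self.pop.ones
        while True:
            i = sector[int(self._u.next() * len(sector))]
            if self._u.next() * L < ones[i]:
                return i

    def _do_birth(self) -> int:
        pop, p = self.pop, self.params
        # sector weights: crowd*S_v/L vs crowd*beta*S_c/L — the crowd/L factor
        # cancels in the proportion
        w_v = pop.S_ones[0]
        w_c = p.beta * pop.S_ones[1]
        if self._u.next() * (w_v + w_c) < w_v:
            parent = self._pick_by_ones(pop.sector[_VEG])
        else:
            parent = self._pick_by_ones(pop.sector[_COMP])
        if self._mutating:
            daughter = mutate_genome(pop.genomes[parent], p, self.rng)
            ones = int(daughter.sum())
        else:
            daughter = pop.genomes[parent]
            ones = pop.ones[parent]
        pop.clone_add(daughter, ones, parent)
        self._last_target = parent
        return _EV_BIRTH

    def _do_death(self) -> int:
        pop, p = self.pop, self.params
        w_v = len(pop.sector[_VEG])
        w_c = p.beta * len(pop.sector[_COMP])
        if self._u.next() * (w_v + w_c) < w_v:
            victim = self._pick_uniform(pop.sector[_VEG])
        else:
            victim = self._pick_uniform(pop.sector[_COMP])
        self._last_target = victim
        self._last_lineage = int(pop.lineage[victim])
        pop.remove_cell(victim)
        return _EV_DEATH

    def _do_switch_in(self) -> int:
        pop = self.pop
        veg = pop.sector[_VEG]
        kin = pop.kin
        env = pop.max_kin
        while True:
            i = veg[int(self._u.next() * len(veg))]
            if self._u.next() * env < kin[i]:
                break
        pop.set_phenotype(i, _COMP)
        self._last_target = i
        return _EV_SWITCH_IN

    def _do_switch_out(self) -> int:
        pop = self.pop
        comp = pop.sector[_COMP]
        kout = pop.kout
        env = pop.max_kout
        while True:
            i = comp[int(self._u.next() * len(comp))]
            if self._u.next() * env < kout[i]:
                break
        pop.set_phenotype(i, _VEG)
        self._last_target = i
        return _EV_SWITCH_OUT

    def _do_recombination(self) -> int:
        pop, p = self.pop, self.params
        acceptor = self._pick_uniform(pop.sector[_COMP])
        locus = int(self._u.next() * p.L)
        if p.pool_lambda > 0.0 and self._u.next() < p.pool_lambda:
            allele = 0
        else:
            # donor allele: the allele at `locus` of a uniformly random living
            # cell (acceptor included) — the pool mirrors the population
            n_v = len(pop.sector[_VEG])
            if self._u.next() * pop.N < n_v:
                donor = self._pick_uniform(pop.sector[_VEG])
            else:
                donor = self._pick_uniform(pop.sector[_COMP])
            allele = int(pop.genomes[donor, locus])
        pop.set_allele(acceptor, locus, allele)
        self._last_target = acceptor
        return _EV_RECOMBINATION

    # -- driver -----------------------------------------------------------

    def run(self, t_max: float | None = None, max_events: int | None = None,
            stop_mean_ones: float | None = None,
            stop_lineage: int | None = None,
            thresholds=(), stride: float | None = None,
            visit_hook=None) -> RunResult:
        """Run until a stop criterion fires.

        Stop criteria (any combination): ``t_max`` (clock), ``max_events``
        (protective cap, termination flagged as truncation),
        ``stop_mean_ones`` (population mean ones crosses the value from
        below), ``stop_lineage`` (the given lineage label reaches count 0 or
        N — fixation/extinction).  ``thresholds`` is a sequence of mean-ones
        values whose first upward crossing times (and cumulative birth
        counts) are recorded.  ``stride`` samples a summary row at that
        clock spacing.  ``visit_hook(pop, dt)``, if given, is called before
        each event with the holding time spent in the pre-event state.
        """
        pop = self.pop
        t_end = math.inf if t_max is None else pop.t + t_max
        ev_cap = math.inf if max_events is None else max_events
        pending = sorted(th for th in thresholds)
        crossings: dict = {}
        if stop_lineage is not None:
            lin_count = pop.lineage_count(stop_lineage)
        t0 = pop.t
        births0 = int(self.event_counts[int(EventType.BIRTH)])
        tint0 = self.tint
        tint_N0, tint_c0, tint_o0 = self.tint_N, self.tint_comp, self.tint_ones

        rows = [self._traj_row()]
        next_rec = pop.t + stride if stride is not None else math.inf

        termination = None
        truncated = False
        n_events = 0
        # check stop conditions that may already hold at entry
        if stop_mean_ones is not None and pop.mean_ones >= stop_mean_ones:
            termination = "mean_ones"
        if stop_lineage is not None and termination is None:
            if lin_count == 0:
                termination = "lineage_extinct"
            elif lin_count == pop.N:
                termination = "lineage_fixed"
        if t_max is not None and t_max <= 0 and termination is None:
            termination = "t_max"

        while termination is None:
            out = self.step()
            if out is ABSORBED:
                termination = "absorbed"
                break
            ev, dt = out
            if visit_hook is not None:
                # dt is the holding time spent in the *pre-event* state; the
                # hook sees the post-event population and is responsible for
                # lagging its own state extraction by one call.
                visit_hook(pop, dt)
            n_events += 1
            # threshold crossings on the mean number of ones
            if pending:
                mo = pop.mean_ones
                while pending and mo >= pending[0]:
                    th = pending.pop(0)
                    crossings[th] = {
                        "t": pop.t,
                        "births": int(self.event_counts[int(EventType.BIRTH)])
                        - births0,
                    }
            if pop.t >= next_rec:
                rows.append(self._traj_row())
                while next_rec <= pop.t:
                    next_rec += stride
            # stop criteria
            if stop_lineage is not None:
                if ev == EventType.BIRTH:
                    if int(pop.lineage[self._last_target]) == stop_lineage:
                        lin_count += 1
                elif ev == EventType.DEATH:
                    if self._last_lineage == stop_lineage:
                        lin_count -= 1
                if lin_count == 0:
                    termination = "lineage_extinct"
                elif lin_count == pop.N and pop.N > 0:
                    termination = "lineage_fixed"
            if termination is None and stop_mean_ones is not None \
                    and pop.mean_ones >= stop_mean_ones:
                termination = "mean_ones"
            if termination is None and pop.t >= t_end:
                termination = "t_max"
            if termination is None and n_events >= ev_cap:
                termination = "max_events"
                truncated = True

        rows.append(self._traj_row())
        traj = np.array(rows, dtype=_TRAJ_DTYPE).view(np.recarray)
        elapsed = self.tint - tint0
        if elapsed > 0:
            avg_N = (self.tint_N - tint_N0) / elapsed
            avg_pc_num = (self.tint_comp - tint_c0) / elapsed
            avg_pc = avg_pc_num / avg_N if avg_N > 0 else 0.0
            avg_ones = (self.tint_ones - tint_o0) / elapsed
        else:
            avg_N = float(pop.N)
            avg_pc = pop.competent_fraction
            avg_ones = pop.mean_ones
        births = int(self.event_counts[int(EventType.BIRTH)]) - births0
        generations = births / avg_N if avg_N > 0 else 0.0
        return RunResult(
            termination=termination,
            trajectory=traj,
            crossings=crossings,
            event_counts=np.array(self.event_counts, dtype=np.int64),
            time_avg_N=avg_N,
            time_avg_pc=avg_pc,
            time_avg_mean_ones=avg_ones,
            elapsed=elapsed,
            generations=generations,
            truncated=truncated,
        )

    def _traj_row(self):
        pop = self.pop
        c = self.event_counts
        return (pop.t, pop.N, pop.n_competent, pop.mean_ones,
                c[0], c[1], c[2], c[3], c[4])
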