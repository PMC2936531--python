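"""Finite-population deterministic fitness-class model.

Instead of tracking genotypes, cells are binned by fitness class
``x_j = j / L`` (the fraction of ones), with ``n_j`` vegetative and ``m_j``
competent cells in class ``j``.  The dynamics combine four operators:

* growth ``G``: per-class net growth ``[b_j * theta(n_j - 1) - delta] n_j``
  with the logistic birth rate ``b_j = x_j (1 - N/K)``.  The Heaviside
  factor ``theta`` shuts birth off in classes occupied by fewer than one
  cell — a heuristic noise cutoff that stops fractional numbers of very fit
  cells from sweeping, standing in for demographic stochasticity.
* mutation ``M``: single-step fluxes between neighbouring classes, coupled
  to the birth rate because mutation happens at replication.  Deleterious
  flux out of class ``j`` is ``mu_d * j * b_j n_j`` (each of ``j`` ones may
  flip) and beneficial flux is ``mu_b * (L - j) * b_j n_j``.  Multiple
  simultaneous mutations are neglected here (the stochastic engine allows
  them).
* recombination ``R`` (competent sector only): assuming every genotype in a
  fitness class is equally represented, the donor allele is a one with
  probability ``q = (1 - pool_lambda) * phi`` where ``phi`` is the current
  population-mean fraction of ones.  Per-cell move rates are
  ``gamma (1 - x_j) q`` up and ``gamma x_j (1 - q)`` down.
* switching: exchange ``k_in n_j`` / ``k_out m_j`` between the sectors.

The competent sector's growth and mutation are scaled by the persister
factor ``beta``; recombination and switching are not.  Mutation and
recombination conserve total cell number exactly.  Integration is explicit
Euler with an enforced step bound ``dt * max_rate < 0.1``: the cutoff makes
the right-hand side discontinuous, so smooth high-order machinery buys
nothing here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ParamError, SimulationParams

__all__ = [
    "FitnessClassState",
    "growth_operator",
    "mutation_operator",
    "recombination_operator",
    "step_coupled",
    "solve",
    "DeterministicTrajectory",
    "deterministic_velocity",
    "equilibrium_reference",
    "from_population",
    "clone_state",
]


@dataclass
class FitnessClassState:
    """Vegetative (``n``) and competent (``m``) cell numbers per fitness class."""

    n: np.ndarray
    m: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=np.float64)
        self.m = np.asarray(self.m, dtype=np.float64)
        if self.n.shape != self.m.shape or self.n.ndim != 1:
            raise ValueError("n and m must be 1-d vectors of equal length")
        if np.any(self.n < 0) or np.any(self.m < 0):
            raise ValueError("class occupancies must be non-negative")

    @property
    def L(self) -> int:
        return self.n.shape[0] - 1

    @property
    def N(self) -> float:
        return float(self.n.sum() + self.m.sum())

    @property
    def x(self) -> np.ndarray:
        return np.arange(self.L + 1) / self.L

    @property
    def phi(self) -> float:
        """Population-mean fraction of ones."""
        N = self.N
        if N == 0:
            return 0.0
        return float((self.x * (self.n + self.m)).sum() / N)

    @property
    def p_c(self) -> float:
        N = self.N
        return float(self.m.sum() / N) if N else 0.0


def clone_state(state: FitnessClassState) -> FitnessClassState:
    return FitnessClassState(state.n.copy(), state.m.copy(), state.t)


def from_population(pop) -> FitnessClassState:
    """Bin a stochastic population into fitness classes."""
    L = pop.L
    n = np.zeros(L + 1)
    m = np.zeros(L + 1)
    idx = pop.live_indices()
    for i in idx:
        if pop.phen[i] == 0:
            n[pop.ones[i]] += 1
        else:
            m[pop.ones[i]] += 1
    return FitnessClassState(n, m, pop.t)


def _birth_rates(state: FitnessClassState, params: SimulationParams) -> np.ndarray:
    crowd = max(0.0, 1.0 - state.N / params.K)
    return state.x * crowd


def _cutoff(vec: np.ndarray, enabled: bool) -> np.ndarray:
    # occupancy >= 1 counts as "on" (ties included)
    if not enabled:
        return np.ones_like(vec)
    return (vec >= 1.0).astype(np.float64)


def growth_operator(state: FitnessClassState, params: SimulationParams,
                    cutoff: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Per-class time derivatives from birth and death, ``(dn, dm)``.

    The cutoff multiplies only the birth term — death must act on
    sub-unity occupancies too, or mass gets trapped in empty classes.
    """
    b = _birth_rates(state, params)
    dn = (b * _cutoff(state.n, cutoff) - params.delta) * state.n
    dm = params.beta * (b * _cutoff(state.m, cutoff) - params.delta) * state.m
    return dn, dm


def _mutation_flux(vec: np.ndarray, rate: np.ndarray, params: SimulationParams) -> np.ndarray:
    """Nearest-neighbour mutation flux for one sector; conserves mass exactly."""
    L = vec.shape[0] - 1
    j = np.arange(L + 1)
    down = params.mu_d * j * rate * vec          # j -> j-1 (deleterious)
    up = params.mu_b * (L - j) * rate * vec      # j -> j+1 (beneficial)
    d = -(down + up)
    d[:-1] += down[1:]
    d[1:] += up[:-1]
    return d


def mutation_operator(state: FitnessClassState, params: SimulationParams,
                      couple_to_birth: bool = True
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Mutation fluxes between neighbouring classes, ``(dn, dm)``.

    By default the flux is proportional to the class birth rate (mutation
    occurs at replication); ``couple_to_birth=False`` decouples it for
    sensitivity analysis, using a unit per-capita rate instead.  The noise
    cutoff does not enter here: it gates only the net growth term, so even
    a sub-unity class keeps exchanging mutants with its neighbours.
    """
    if couple_to_birth:
        b = _birth_rates(state, params)
        rate_n = b
        rate_m = params.beta * b
    else:
        rate_n = np.ones(state.L + 1)
        rate_m = np.full(state.L + 1, params.beta)
    return (_mutation_flux(state.n, rate_n, params),
            _mutation_flux(state.m, rate_m, params))


def recombination_operator(state: FitnessClassState, params: SimulationParams
                           ) -> np.ndarray:
    """Recombination flux on the competent sector only; conserves mass.

    The donor pool mirrors the instantaneous population (quasi-static), so
    the donor-one probability is ``q = (1 - pool_lambda) * phi`` with
    ``phi`` computed from the full ``n + m`` population.
    """
    x = state.x
    q = (1.0 - params.pool_lambda) * state.phi
    up = params.gamma * (1.0 - x) * q * state.m          # j -> j+1
    down = params.gamma * x * (1.0 - q) * state.m        # j -> j-1
    d = -(up + down)
    d[1:] += up[:-1]
    d[:-1] += down[1:]
    return d


def step_coupled(state: FitnessClassState, params: SimulationParams, dt: float,
                 cutoff: bool = True, couple_to_birth: bool = True,
                 clip_log: list | None = None) -> FitnessClassState:
    """One explicit Euler step of the coupled two-sector system.

    Negative entries produced by the discrete step are clipped to zero and
    the clipped magnitude recorded in ``clip_log`` when provided.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    gn, gm = growth_operator(state, params, cutoff)
    mn, mm = mutation_operator(state, params, couple_to_birth)
    rm = recombination_operator(state, params)
    dn = gn + mn - params.k_in * state.n + params.k_out * state.m
    dm = gm + mm + rm + params.k_in * state.n - params.k_out * state.m
    n = state.n + dt * dn
    m = state.m + dt * dm
    clip = -(n[n < 0].sum() + m[m < 0].sum())
    if clip > 0 and clip_log is not None:
        clip_log.append((state.t + dt, float(clip)))
    np.clip(n, 0.0, None, out=n)
    np.clip(m, 0.0, None, out=m)
    return FitnessClassState(n, m, state.t + dt)


def max_rate_bound(params: SimulationParams) -> float:
    """Crude per-capita bound on the fastest process, for step-size control."""
    b_max = 1.0
    mut = b_max * (params.mu_d * params.L + params.mu_b * params.L)
    return max(
        b_max + mut,
        params.delta,
        params.gamma,
        params.k_in + params.k_out,
    )


@dataclass
class DeterministicTrajectory:
    t: np.ndarray
    N: np.ndarray
    x_mean: np.ndarray
    p_c: np.ndarray
    generations: np.ndarray
    final: FitnessClassState
    clipped_mass: float = 0.0


def solve(initial: FitnessClassState, params: SimulationParams, t_max: float,
          dt: float | None = None, stride: float | None = None,
          cutoff: bool = True, couple_to_birth: bool = True,
          stop_x: float | None = None) -> DeterministicTrajectory:
    """Integrate to ``t_max`` and sample ``(t, N, <x>, p_c, generations)``.

    ``dt`` defaults to ``0.1 / max_rate`` and may only be chosen smaller;
    the generation clock integrates total births per cell per time.  The
    solver is fully deterministic (no RNG anywhere).  ``stop_x`` ends the
    integration early once the mean fraction of ones reaches that level.
    """
    bound = 0.1 / max_rate_bound(params)
    if dt is None:
        dt = bound
    elif dt > bound:
        raise ParamError(
            f"dt={dt} too large: dt * max_rate must stay below 0.1 "
            f"(need dt <= {bound:.3g})"
        )
    if stride is None:
        stride = max(t_max / 500.0, dt)
    state = clone_state(initial)
    clip_log: list = []
    ts, Ns, xs, pcs, gens = [state.t], [state.N], [state.phi], [state.p_c], [0.0]
    gen = 0.0
    next_rec = state.t + stride
    t_end = state.t + t_max
    while state.t < t_end - 1e-12:
        h = min(dt, t_end - state.t)
        # generation clock: births per cell per unit time
        b = _birth_rates(state, params)
        births = float((b * _cutoff(state.n, cutoff) * state.n).sum()
                       + params.beta * (b * _cutoff(state.m, cutoff) * state.m).sum())
        N = state.N
        if N > 0:
            gen += h * births / N
        state = step_coupled(state, params, h, cutoff, couple_to_birth, clip_log)
        phi = state.phi
        record = (state.t >= next_rec - 1e-12 or state.t >= t_end - 1e-12
                  or (stop_x is not None and phi >= stop_x))
        if record:
            ts.append(state.t)
            Ns.append(state.N)
            xs.append(phi)
            pcs.append(state.p_c)
            gens.append(gen)
            while next_rec <= state.t + 1e-12:
                next_rec += stride
        if stop_x is not None and phi >= stop_x:
            break
    return DeterministicTrajectory(
        t=np.array(ts), N=np.array(Ns), x_mean=np.array(xs),
        p_c=np.array(pcs), generations=np.array(gens), final=state,
        clipped_mass=float(sum(c for _, c in clip_log)),
    )


def _first_crossing(t: np.ndarray, y: np.ndarray, level: float) -> float:
    """Time of first upward crossing of ``level``, linearly interpolated."""
    above = y >= level
    if above[0]:
        return float(t[0])
    idx = np.nonzero(above)[0]
    if idx.size == 0:
        raise ValueError(f"trajectory never crosses {level}")
    i = idx[0]
    frac = (level - y[i - 1]) / (y[i] - y[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def deterministic_velocity(traj: DeterministicTrajectory, x_start: float,
                           x_stop: float, per_generation: bool = False) -> float:
    """Adaptation speed in ones per time (or per generation) between two levels."""
    if not x_stop > x_start:
        raise ValueError("x_stop must exceed x_start")
    L = traj.final.L
    clock = traj.generations if per_generation else traj.t
    t1 = _first_crossing(clock, traj.x_mean, x_start)
    t2 = _first_crossing(clock, traj.x_mean, x_stop)
    if t2 <= t1:
        raise ValueError("degenerate crossing interval")
    return L * (x_stop - x_start) / (t2 - t1)


def equilibrium_reference(params: SimulationParams, t_max: float = 20000.0,
                          rtol: float = 1e-8) -> float:
    """Deterministic (no-drift) equilibrium mean fitness, cutoff disabled.

    Integrates the single-sector mutation-selection system from a perfect
    clone with the noise cutoff off and recombination irrelevant (a
    deterministic population is held at linkage equilibrium by assumption),
    and returns the stationary mean fraction of ones.  This is the classical
    mutation-load reference the stochastic equilibrium should be compared
    against: finite populations fall below it when drift bites, and strong
    recombination restores it.
    """
    p = params.replace(gamma=0.0, k_in=0.0, k_out=0.0)
    L = p.L
    n0 = np.zeros(L + 1)
    n0[L] = max(p.K * (1.0 - p.delta), 1.0)
    state = FitnessClassState(n0, np.zeros(L + 1))
    dt = 0.1 / max_rate_bound(p)
    chunk = max(t_max / 20.0, 10 * dt)
    phi_prev = state.phi
    elapsed = 0.0
    while elapsed < t_max:
        traj = solve(state, p, chunk, dt=dt, cutoff=False)
        state = traj.final
        elapsed += chunk
        phi = state.phi
        if abs(phi - phi_prev) <= rtol * max(phi, 1e-12):
            break
        phi_prev = phi
    return state.phi
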