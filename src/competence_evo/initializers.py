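"""Founding populations: clonal, shuffled, and "natural" initial conditions.

All initializers found the population at the stationary census
``N0 = round(K * (1 - delta / f0))`` for founder intrinsic birth rate
``f0 = k1 / L``, so the census is initially neither growing nor shrinking.
A founder with ``f0 <= delta`` cannot sustain a population and is rejected.

* ``init_clonal`` — every founder carries the identical genome with ``k1``
  ones (positions drawn once and shared): zero initial diversity.
* ``init_shuffled`` — each founder independently receives ``k1`` ones at
  random distinct loci: the maximal diversity compatible with a fixed
  founder fitness.
* ``init_natural`` — a perfect clone is burned in to mutation/selection/
  drift equilibrium, then the same randomly chosen ``F`` loci are flipped in
  every cell, emulating a sudden environmental change that displaces the
  population from its fitness peak while preserving standing diversity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import ParamError, Phenotype, Population, SimulationParams
from .engine import GillespieEngine, RunResult

__all__ = [
    "stationary_size",
    "init_clonal",
    "init_shuffled",
    "init_natural",
    "make_fixture",
    "burn_in_is_stationary",
    "NaturalInitResult",
]


def stationary_size(params: SimulationParams, k1: int) -> int:
    """Founding census at which birth balances death for founder fitness k1/L."""
    if not (0 <= k1 <= params.L):
        raise ParamError(f"k1 must be in [0, {params.L}], got {k1}")
    f0 = k1 / params.L
    if f0 <= params.delta:
        raise ParamError(
            f"founder fitness k1/L = {f0:.4g} must exceed delta = {params.delta:.4g}"
            " for a viable population"
        )
    n0 = int(round(params.K * (1.0 - params.delta / f0)))
    return max(n0, 1)


def _founding_pop(params: SimulationParams, n0: int) -> Population:
    cap = max(n0 + 8, min(int(np.ceil(params.K)) + 8, 4096))
    return Population(params, capacity=cap)


def init_clonal(k1: int, params: SimulationParams, rng: np.random.Generator,
                phenotype: Phenotype = Phenotype.VEGETATIVE) -> Population:
    """Monomorphic founding population: one shared genome with ``k1`` ones."""
    n0 = stationary_size(params, k1)
    loci = rng.choice(params.L, size=k1, replace=False)
    genome = np.zeros(params.L, dtype=np.uint8)
    genome[loci] = 1
    pop = _founding_pop(params, n0)
    for _ in range(n0):
        pop.add_cell(genome, phenotype)
    return pop


def init_shuffled(k1: int, params: SimulationParams, rng: np.random.Generator,
                  phenotype: Phenotype = Phenotype.VEGETATIVE) -> Population:
    """Each founder gets ``k1`` ones at independently random distinct loci."""
    n0 = stationary_size(params, k1)
    pop = _founding_pop(params, n0)
    for _ in range(n0):
        genome = np.zeros(params.L, dtype=np.uint8)
        genome[rng.choice(params.L, size=k1, replace=False)] = 1
        pop.add_cell(genome, phenotype)
    return pop


@dataclass
class NaturalInitResult:
    population: Population
    burn_in: RunResult
    flipped_loci: np.ndarray


class BurnInExtinction(RuntimeError):
    """Population went extinct during burn-in; the trajectory is attached."""

    def __init__(self, result: RunResult) -> None:
        super().__init__("population went extinct during burn-in")
        self.result = result


def init_natural(params: SimulationParams, burn_in_time: float, flip_count: int,
                 rng: np.random.Generator,
                 burn_in_gamma: float | None = None,
                 phenotype: Phenotype = Phenotype.VEGETATIVE,
                 stride: float | None = None) -> NaturalInitResult:
    """Burn a perfect clone to equilibrium, then flip ``flip_count`` loci everywhere.

    The loci are chosen once, uniformly without replacement, and flipped in
    every living cell, so the census and phenotype composition are untouched
    and only genomes change.  ``burn_in_gamma`` overrides the recombination
    rate used during the burn-in (it reverts to ``params.gamma`` afterwards,
    i.e. for the returned population's parameter set).
    """
    if not (0 <= flip_count <= params.L):
        raise ParamError(f"flip_count must be in [0, {params.L}], got {flip_count}")
    burn_params = params if burn_in_gamma is None \
        else params.replace(gamma=burn_in_gamma)
    pop = init_clonal(params.L, burn_params, rng, phenotype=phenotype)
    engine = GillespieEngine(pop, burn_params, rng)
    if stride is None:
        stride = max(burn_in_time / 200.0, 1e-9)
    result = engine.run(t_max=burn_in_time, stride=stride)
    if pop.N == 0:
        raise BurnInExtinction(result)
    loci = rng.choice(params.L, size=flip_count, replace=False)
    if flip_count:
        pop.flip_loci_everywhere(loci)
    pop.params = params
    return NaturalInitResult(population=pop, burn_in=result, flipped_loci=loci)


def burn_in_is_stationary(result: RunResult, tail_fraction: float = 0.25,
                          alpha: float = 0.05) -> bool:
    """QC: no linear trend in mean ones over the final part of the burn-in.

    Regresses mean ones on time over the last ``tail_fraction`` of the
    recorded trajectory and requires the slope's t-test p-value > ``alpha``.
    """
    traj = result.trajectory
    n = len(traj)
    tail = traj[int(n * (1.0 - tail_fraction)):]
    if len(tail) < 3:
        raise ValueError("trajectory too short for a trend test")
    if np.allclose(tail.mean_ones, tail.mean_ones[0]):
        return True
    fit = stats.linregress(tail.t, tail.mean_ones)
    return bool(fit.pvalue > alpha)


def make_fixture(params: SimulationParams, cells, t: float = 0.0) -> Population:
    """Exact population from an explicit list of :class:`~.core.Cell`."""
    return Population.from_cells(params, cells, t=t)
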