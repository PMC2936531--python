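"""Experiment protocols: adaptation velocity, equilibrium fitness, invasions.

Three seeded, replicate-driven protocols measure evolutionary success:

* **velocity** — found a population at a fixed fitness (clonal, shuffled or
  natural diversity), let it climb, and measure the speed at which the
  population-mean number of ones passes between two thresholds.  The
  per-generation variant divides by the realised birth events per cell.
* **equilibrium** — found a perfect clone and let mutation, selection and
  drift balance; report the time-averaged mean fraction of ones over a
  final window, next to the no-drift deterministic reference.
* **competition** — convert a few random residents into labelled invaders
  with a different competence strategy and repeat until the invader lineage
  fixes or dies out; the fixation probability against the invader count
  gives the scaled selection coefficient Ns through the slope of a linear
  fit, and its linearity is the frequency-independence diagnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import spawn_rngs
from .core import ParamError, Phenotype, Population, SimulationParams
from .deterministic import (
    FitnessClassState,
    deterministic_velocity,
    equilibrium_reference,
    solve,
)
from .engine import GillespieEngine
from .initializers import init_clonal, init_natural, init_shuffled

__all__ = [
    "VelocityEstimate",
    "EquilibriumResult",
    "CompetitionResult",
    "PfixFit",
    "measure_velocity",
    "run_equilibrium",
    "make_resident_bank",
    "run_competition",
    "fit_pfix_vs_n0",
    "sweep_competent_fraction",
    "deterministic_velocity_for",
]

_INVADER_LINEAGE = 1


@dataclass
class VelocityEstimate:
    v_mean: float
    v_se: float
    per_replicate: list  # (replicate index, v, t_start, t_stop)
    regime: str
    per_generation: bool
    n_excluded: int = 0

    @property
    def n_replicates(self) -> int:
        return len(self.per_replicate)


def _apply_policy(pop: Population, idx, policy: str, params: SimulationParams) -> None:
    """Set phenotype and per-cell switching rates for the given slots."""
    if policy == "vegetative":
        kin, kout, phen = 0.0, 0.0, Phenotype.VEGETATIVE
    elif policy == "competent":
        kin, kout, phen = 0.0, 0.0, Phenotype.COMPETENT
    elif policy == "switching":
        kin, kout, phen = params.k_in, params.k_out, Phenotype.VEGETATIVE
    else:
        raise ValueError(f"unknown phenotype policy {policy!r}")
    for i in idx:
        pop.kin[i] = kin
        pop.kout[i] = kout
        pop.set_phenotype(i, phen)
    if kin > pop.max_kin:
        pop.max_kin = kin
    if kout > pop.max_kout:
        pop.max_kout = kout
    pop.resync_rate_caches()


def _make_initial(initializer: str, k1: int, params: SimulationParams,
                  rng: np.random.Generator, policy: str,
                  burn_in_time: float = 0.0, flip_count: int = 0,
                  burn_in_gamma: float | None = None) -> Population:
    phen = Phenotype.COMPETENT if policy == "competent" else Phenotype.VEGETATIVE
    if initializer == "clonal":
        pop = init_clonal(k1, params, rng, phenotype=phen)
    elif initializer == "shuffled":
        pop = init_shuffled(k1, params, rng, phenotype=phen)
    elif initializer == "natural":
        res = init_natural(params, burn_in_time, flip_count, rng,
                           burn_in_gamma=burn_in_gamma, phenotype=phen)
        pop = res.population
    else:
        raise ValueError(f"unknown initializer {initializer!r}")
    if policy == "switching":
        _apply_policy(pop, pop.live_indices(), "switching", params)
    return pop


def measure_velocity(params: SimulationParams, initializer: str, k1: int,
                     k_lo: float, k_hi: float, replicates: int,
                     seed: int | None = None,
                     phenotype_policy: str = "competent",
                     per_generation: bool = False,
                     t_cap: float = 1e5, max_events: int | None = None,
                     burn_in_time: float = 0.0, flip_count: int = 0,
                     burn_in_gamma: float | None = None) -> VelocityEstimate:
    """Adaptation speed between two mean-ones thresholds, over replicates.

    ``v = (k_hi - k_lo) / (t(k_hi) - t(k_lo))`` with first-crossing times of
    the population mean; replicates that never reach ``k_hi`` (Muller's
    ratchet regime, extinction, or the event cap) are excluded and counted
    in ``n_excluded``.
    """
    if not (k_lo < k_hi <= params.L):
        raise ParamError("need k_lo < k_hi <= L")
    rngs = spawn_rngs(params.seed if seed is None else seed, replicates)
    per_rep = []
    excluded = 0
    for r, rng in enumerate(rngs):
        pop = _make_initial(initializer, k1, params, rng, phenotype_policy,
                            burn_in_time, flip_count, burn_in_gamma)
        engine = GillespieEngine(pop, params, rng)
        res = engine.run(thresholds=[k_lo, k_hi], stop_mean_ones=k_hi,
                         t_max=t_cap, max_events=max_events)
        if k_lo not in res.crossings or k_hi not in res.crossings:
            excluded += 1
            continue
        c_lo, c_hi = res.crossings[k_lo], res.crossings[k_hi]
        if per_generation:
            # generations = cumulative birth events / time-averaged census
            dg = (c_hi["births"] - c_lo["births"]) / res.time_avg_N
            v = (k_hi - k_lo) / dg
        else:
            v = (k_hi - k_lo) / (c_hi["t"] - c_lo["t"])
        per_rep.append((r, v, c_lo["t"], c_hi["t"]))
    if per_rep:
        vs = np.array([p[1] for p in per_rep])
        v_mean = float(vs.mean())
        v_se = float(vs.std(ddof=1) / math.sqrt(len(vs))) if len(vs) > 1 else 0.0
    else:
        v_mean, v_se = math.nan, math.nan
    return VelocityEstimate(v_mean=v_mean, v_se=v_se, per_replicate=per_rep,
                            regime=initializer, per_generation=per_generation,
                            n_excluded=excluded)


def _det_initial_state(params: SimulationParams, k1: int,
                       phenotype_policy: str) -> FitnessClassState:
    L = params.L
    n0_total = params.K * (1.0 - params.delta / (k1 / L))
    if n0_total <= 0:
        raise ParamError("founder fitness below the viability threshold")
    n = np.zeros(L + 1)
    m = np.zeros(L + 1)
    if phenotype_policy == "competent":
        m[k1] = n0_total
    elif phenotype_policy == "vegetative":
        n[k1] = n0_total
    elif phenotype_policy == "switching":
        tot = params.k_in + params.k_out
        pc = params.k_in / tot if tot > 0 else 0.0
        m[k1] = pc * n0_total
        n[k1] = (1 - pc) * n0_total
    else:
        raise ValueError(f"unknown phenotype policy {phenotype_policy!r}")
    return FitnessClassState(n, m)


def deterministic_velocity_for(params: SimulationParams, k1: int, k_lo: float,
                               k_hi: float, phenotype_policy: str = "competent",
                               t_max: float = 2e4, cutoff: bool = True,
                               per_generation: bool = False) -> float:
    """Deterministic-solver counterpart of :func:`measure_velocity`.

    The founding state concentrates the stationary census in class ``k1``;
    with the "switching" policy the two sectors start at the neutral
    switching split ``k_in/(k_in+k_out)``.  Integration stops as soon as
    the upper threshold is reached.
    """
    L = params.L
    initial = _det_initial_state(params, k1, phenotype_policy)
    traj = solve(initial, params, t_max, cutoff=cutoff, stop_x=k_hi / L)
    return deterministic_velocity(traj, k_lo / L, k_hi / L,
                                  per_generation=per_generation)


@dataclass
class EquilibriumResult:
    phi_mean: float
    phi_se: float
    per_replicate: list
    deterministic_reference: float
    n_extinct: int = 0


def run_equilibrium(params: SimulationParams, t_total: float, window: float,
                    replicates: int, seed: int | None = None,
                    phenotype_policy: str = "competent") -> EquilibriumResult:
    """Equilibrium mean fitness from perfect-clone foundings.

    Each replicate starts as a perfect clone at the stationary census, runs
    for ``t_total``, and contributes the time-average of the mean fraction
    of ones over the final ``window``.  The no-drift reference is computed
    numerically from the deterministic model with the cutoff disabled.
    """
    if not (0 < window < t_total):
        raise ParamError("need 0 < window < t_total")
    rngs = spawn_rngs(params.seed if seed is None else seed, replicates)
    per_rep = []
    extinct = 0
    for r, rng in enumerate(rngs):
        pop = _make_initial("clonal", params.L, params, rng, phenotype_policy)
        engine = GillespieEngine(pop, params, rng)
        engine.run(t_max=t_total - window)
        if pop.N == 0:
            extinct += 1
            continue
        tail = engine.run(t_max=window)
        if pop.N == 0:
            extinct += 1
            continue
        per_rep.append((r, tail.time_avg_mean_ones / params.L))
    if per_rep:
        phis = np.array([p[1] for p in per_rep])
        phi_mean = float(phis.mean())
        phi_se = float(phis.std(ddof=1) / math.sqrt(len(phis))) \
            if len(phis) > 1 else 0.0
    else:
        phi_mean, phi_se = math.nan, math.nan
    ref = equilibrium_reference(params)
    return EquilibriumResult(phi_mean=phi_mean, phi_se=phi_se,
                             per_replicate=per_rep,
                             deterministic_reference=ref, n_extinct=extinct)


def make_resident_bank(params: SimulationParams, n_pops: int, seed: int,
                       mode: str = "adapting", k_start: int | None = None,
                       k_save: float | None = None,
                       t_equilibrate: float | None = None,
                       phenotype_policy: str = "vegetative"
                       ) -> list[Population]:
    """Saved resident populations for competitions.

    ``adapting`` banks found a clone at ``k_start`` ones and save the
    population when its mean ones first crosses ``k_save`` (mid-climb,
    semi-natural diversity).  ``equilibrium`` banks found a perfect clone
    and save after ``t_equilibrate``.
    """
    rngs = spawn_rngs(seed, n_pops)
    bank = []
    for rng in rngs:
        if mode == "adapting":
            if k_start is None or k_save is None:
                raise ParamError("adapting bank needs k_start and k_save")
            pop = _make_initial("clonal", k_start, params, rng, phenotype_policy)
            engine = GillespieEngine(pop, params, rng)
            res = engine.run(stop_mean_ones=k_save, t_max=1e6)
            if res.termination != "mean_ones":
                raise RuntimeError(
                    f"bank population never reached {k_save} ({res.termination})"
                )
        elif mode == "equilibrium":
            if t_equilibrate is None:
                raise ParamError("equilibrium bank needs t_equilibrate")
            pop = _make_initial("clonal", params.L, params, rng, phenotype_policy)
            engine = GillespieEngine(pop, params, rng)
            engine.run(t_max=t_equilibrate)
            if pop.N == 0:
                raise RuntimeError("bank population went extinct")
        else:
            raise ValueError(f"unknown bank mode {mode!r}")
        bank.append(pop)
    return bank


def save_bank(bank: list[Population], directory) -> None:
    """Serialize a resident/burn-in bank to a directory of text files."""
    from pathlib import Path

    from .popio import write_population
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for i, pop in enumerate(bank):
        write_population(pop, d / f"population_{i:03d}.txt")


def load_bank(directory, params: SimulationParams) -> list[Population]:
    from pathlib import Path

    from .popio import read_population
    d = Path(directory)
    files = sorted(d.glob("population_*.txt"))
    if not files:
        raise FileNotFoundError(f"no bank populations under {d}")
    return [read_population(f, params) for f in files]


def sample_bank(bank: list[Population], rng: np.random.Generator) -> Population:
    """Seeded draw of one saved population (copied, safe to mutate)."""
    return bank[int(rng.integers(len(bank)))].copy()


@dataclass
class CompetitionResult:
    n0: int
    replicates: int
    fixations: int
    p_fix: float
    p_fix_ci: tuple
    N_bar: float
    descendants: float
    invader_policy: str
    resident_policy: str
    n_censored: int = 0

    @property
    def p_fix_se(self) -> float:
        n = self.replicates
        return math.sqrt(self.p_fix * (1 - self.p_fix) / n) if n else math.nan


def run_competition(resident_bank: list[Population], invader_policy: str, n0: int,
                    replicates: int, seed: int,
                    params: SimulationParams | None = None,
                    resident_policy: str = "vegetative",
                    max_events: int = 50_000_000,
                    ci_level: float = 0.95) -> CompetitionResult:
    """Invasion experiment: fixation probability of ``n0`` converted cells.

    Each replicate copies a randomly chosen resident population, relabels
    ``n0`` random cells as invaders (keeping their genomes — invaders appear
    in randomly sampled genetic backgrounds) and applies the invader's
    competence strategy.  Lineage labels never change, so invaders and
    residents cannot convert into one another.  The run ends when the
    invader lineage is absorbed at 0 or N; hitting the protective event cap
    counts the replicate as censored, reported but excluded from ``p_fix``.
    """
    if not resident_bank:
        raise ValueError("resident bank is empty")
    if params is None:
        params = resident_bank[0].params
    rngs = spawn_rngs(seed, replicates)
    fixations = 0
    censored = 0
    effective = 0
    n_at_start = []
    for rng in rngs:
        src = resident_bank[int(rng.integers(len(resident_bank)))]
        pop = src.copy()
        idx = rng.choice(pop.live_indices(), size=n0, replace=False)
        pop.lineage[idx] = _INVADER_LINEAGE
        _apply_policy(pop, idx, invader_policy, params)
        n_at_start.append(pop.N)
        engine = GillespieEngine(pop, params, rng)
        res = engine.run(stop_lineage=_INVADER_LINEAGE, max_events=max_events)
        if res.termination == "lineage_fixed":
            fixations += 1
            effective += 1
        elif res.termination in ("lineage_extinct", "absorbed"):
            # full extinction also ends the invader lineage
            effective += 1
        else:
            censored += 1
    p_fix = fixations / effective if effective else math.nan
    ci = stats.binomtest(fixations, effective).proportion_ci(
        confidence_level=ci_level, method="exact") if effective else (math.nan,) * 2
    n_bar = float(np.mean(n_at_start))
    descendants = p_fix / (n0 / n_bar) if n_bar > 0 else math.nan
    return CompetitionResult(
        n0=n0, replicates=effective, fixations=fixations, p_fix=p_fix,
        p_fix_ci=(float(ci[0]), float(ci[1])), N_bar=n_bar,
        descendants=descendants, invader_policy=invader_policy,
        resident_policy=resident_policy, n_censored=censored,
    )


@dataclass
class PfixFit:
    slope: float
    slope_se: float
    intercept: float
    Ns: float
    lack_of_fit_p: float
    saturating_rate: float
    saturating_better: bool


def fit_pfix_vs_n0(results: list[CompetitionResult]) -> PfixFit:
    """Least-squares line through ``p_fix(n0)`` and a frequency-dependence check.

    ``Ns = slope * N_bar`` scales the per-invader advantage; under
    frequency-independent selection each invader fixes independently, so
    ``p_fix`` is linear in ``n0`` while it is small.  The lack-of-fit
    statistic compares observed fixation counts with the line's binomial
    expectation (chi-square, ``k - 2`` df); a saturating alternative
    ``p = 1 - (1 - r)^{n0}`` is fitted by maximum likelihood for comparison.
    """
    if len({r.n0 for r in results}) < 3:
        raise ValueError("need >= 3 distinct n0 values")
    n0 = np.array([r.n0 for r in results], dtype=float)
    p = np.array([r.p_fix for r in results])
    k = np.array([r.fixations for r in results], dtype=float)
    n = np.array([r.replicates for r in results], dtype=float)
    fit = stats.linregress(n0, p)
    n_bar = float(np.mean([r.N_bar for r in results]))
    # sampling error of the OLS slope, propagated from the known binomial
    # variance of each p_hat (the residual-based estimate is useless at
    # 1-2 degrees of freedom)
    x_c = n0 - n0.mean()
    coef = x_c / (x_c ** 2).sum()
    var_p = np.clip(p * (1 - p), 1e-12, None) / n
    slope_se = float(np.sqrt((coef ** 2 * var_p).sum()))
    # lack of fit of the linear null
    p_hat = np.clip(fit.intercept + fit.slope * n0, 1e-12, 1 - 1e-12)
    chi2 = float(np.sum((k - n * p_hat) ** 2 / (n * p_hat * (1 - p_hat))))
    dof = len(results) - 2
    lof_p = float(stats.chi2.sf(chi2, dof)) if dof > 0 else math.nan

    def negll(logit_r):
        r = 1.0 / (1.0 + math.exp(-logit_r))
        q = np.clip(1.0 - (1.0 - r) ** n0, 1e-12, 1 - 1e-12)
        return -float(np.sum(k * np.log(q) + (n - k) * np.log(1 - q)))

    opt = optimize.minimize_scalar(negll, bounds=(-15, 5), method="bounded")
    r_hat = 1.0 / (1.0 + math.exp(-opt.x))
    q = np.clip(1.0 - (1.0 - r_hat) ** n0, 1e-12, 1 - 1e-12)
    ll_sat = float(np.sum(k * np.log(q) + (n - k) * np.log(1 - q)))
    ll_lin = float(np.sum(k * np.log(p_hat) + (n - k) * np.log(1 - p_hat)))
    return PfixFit(
        slope=float(fit.slope), slope_se=slope_se,
        intercept=float(fit.intercept), Ns=float(fit.slope * n_bar),
        lack_of_fit_p=lof_p, saturating_rate=r_hat,
        saturating_better=ll_sat > ll_lin + 2.0,
    )


def sweep_competent_fraction(params_base: SimulationParams, kin_grid,
                             k_out: float, k1: int, k_lo: float, k_hi: float,
                             replicates: int = 0, seed: int = 0,
                             use_deterministic: bool = False,
                             t_cap: float = 1e5,
                             det_t_max: float = 2e4,
                             bootstrap: int = 2000) -> pd.DataFrame:
    """Velocity against the competent fraction ``p_c = k_in / (k_in + k_out)``.

    Each grid point measures both the per-time and per-generation speed for
    a stochastically switching population.  With ``use_deterministic`` the
    fitness-class solver supplies the curve (fast, noise-free); otherwise
    ``replicates`` stochastic runs per point.  Returns a tidy table with
    one row per grid point.
    """
    rows = []
    for g, kin in enumerate(kin_grid):
        p = params_base.replace(k_in=float(kin), k_out=float(k_out))
        pc = kin / (kin + k_out) if (kin + k_out) > 0 else 0.0
        if use_deterministic:
            initial = _det_initial_state(p, k1, "switching")
            traj = solve(initial, p, det_t_max, stop_x=k_hi / p.L)
            v = deterministic_velocity(traj, k_lo / p.L, k_hi / p.L)
            vg = deterministic_velocity(traj, k_lo / p.L, k_hi / p.L,
                                        per_generation=True)
            rows.append({"k_in": kin, "p_c": pc, "v": v, "v_se": 0.0,
                         "v_per_generation": vg, "n_replicates": 0})
        else:
            est = measure_velocity(p, "shuffled", k1, k_lo, k_hi, replicates,
                                   seed=seed + g, phenotype_policy="switching",
                                   t_cap=t_cap)
            est_g = measure_velocity(p, "shuffled", k1, k_lo, k_hi, replicates,
                                     seed=seed + g, phenotype_policy="switching",
                                     per_generation=True, t_cap=t_cap)
            rows.append({"k_in": kin, "p_c": pc, "v": est.v_mean,
                         "v_se": est.v_se, "v_per_generation": est_g.v_mean,
                         "n_replicates": est.n_replicates})
    return pd.DataFrame(rows)


def bootstrap_argmax_pc(table: pd.DataFrame, per_replicate: dict,
                        n_boot: int = 2000, seed: int = 0,
                        level: float = 0.90) -> tuple[float, float, float]:
    """Bootstrap interval for the p_c that maximises v.

    ``per_replicate`` maps each grid p_c to its replicate velocity list;
    resampling replicates within each point gives the argmax distribution.
    """
    rng = np.random.default_rng(seed)
    pcs = np.array(sorted(per_replicate))
    arg = []
    for _ in range(n_boot):
        means = []
        for pc in pcs:
            vs = np.asarray(per_replicate[pc])
            means.append(rng.choice(vs, size=len(vs), replace=True).mean())
        arg.append(pcs[int(np.argmax(means))])
    arg = np.array(arg)
    lo = float(np.quantile(arg, (1 - level) / 2))
    hi = float(np.quantile(arg, 1 - (1 - level) / 2))
    point = float(pcs[int(np.argmax([np.mean(per_replicate[pc]) for pc in pcs]))])
    return point, lo, hi
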