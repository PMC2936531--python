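"""Stochastic engine: rates, event selection, mutation, recombination, runs."""

import math

import numpy as np
import pytest
from scipy import stats

from competence_evo import (
    ABSORBED,
    Cell,
    EventType,
    Genome,
    GillespieEngine,
    Phenotype,
    Population,
    SimulationParams,
    compute_rates,
    mutate_genome,
)
from competence_evo.initializers import init_clonal


def make_pop(params, cells):
    return Population.from_cells(params, cells)


class TestComputeRates:
    def test_two_vegetative_all_ones(self):
        p = SimulationParams(L=4, K=4.0, delta=0.1)
        pop = make_pop(p, [Cell(Genome.from_bitstring("1111"))] * 2)
        r = compute_rates(pop, p)
        assert r.birth_total == pytest.approx(2 * 1.0 * (1 - 2 / 4))
        assert r.death_total == pytest.approx(0.2)
        assert r.recomb_total == 0.0
        assert r.grand_total == pytest.approx(1.2)

    def test_single_competent_cell(self):
        p = SimulationParams(L=4, K=1e12, delta=0.1, beta=0.5, gamma=0.3,
                             k_out=0.2)
        pop = make_pop(p, [Cell(Genome.from_bitstring("1111"),
                                Phenotype.COMPETENT)])
        r = compute_rates(pop, p)
        assert r.birth_total == pytest.approx(0.5, rel=1e-9)
        assert r.death_total == pytest.approx(0.05)
        assert r.recomb_total == pytest.approx(0.3)
        assert r.switch_out_total == pytest.approx(0.2)

    def test_empty_population_all_zero(self):
        p = SimulationParams(L=4, K=10.0)
        pop = Population(p)
        r = compute_rates(pop, p)
        assert r.grand_total == 0.0

    def test_engine_cache_matches_reference(self, rng):
        p = SimulationParams(L=6, K=40.0, delta=0.2, beta=0.4, mu_d=0.05,
                             mu_b=0.02, k_in=0.3, k_out=0.5, gamma=0.7)
        pop = init_clonal(5, p, rng)
        engine = GillespieEngine(pop, p, rng)
        for _ in range(500):
            if engine.step() is ABSORBED:
                break
        ref = compute_rates(pop, p)
        now = engine.rates()
        assert now.grand_total == pytest.approx(ref.grand_total, rel=1e-9)
        assert now.birth_total == pytest.approx(ref.birth_total, rel=1e-9)


class TestStep:
    def test_forced_death_when_only_death_possible(self, rng):
        # all-zero genomes cannot replicate; no switching/recombination
        p = SimulationParams(L=3, K=100.0, delta=0.5)
        pop = make_pop(p, [Cell(Genome.from_bitstring("000"))] * 5)
        engine = GillespieEngine(pop, p, rng)
        seen = set()
        while (out := engine.step()) is not ABSORBED:
            seen.add(out[0])
        assert seen == {int(EventType.DEATH)}
        assert pop.N == 0

    def test_absorbed_on_empty(self, rng):
        p = SimulationParams(L=3, K=100.0)
        engine = GillespieEngine(Population(p), p, rng)
        assert engine.step() is ABSORBED

    def test_fitter_cell_replicates_two_thirds(self, rng):
        """f=1.0 vs f=0.5 at N<<K: fitter parent chosen w.p. 2/3."""
        p = SimulationParams(L=2, K=1e9, delta=0.0)
        pop = make_pop(p, [Cell(Genome.from_bitstring("11")),
                           Cell(Genome.from_bitstring("10"))])
        engine = GillespieEngine(pop, p, rng)
        n = 100_000
        fit_parent = 0
        for _ in range(n):
            engine.step()
            born = pop.live_indices()[-1]
            if pop.ones[born] == 2:
                fit_parent += 1
            pop.remove_cell(born)  # keep the two-cell setup
        phat = fit_parent / n
        se = math.sqrt((2 / 3) * (1 / 3) / n)
        assert abs(phat - 2 / 3) < 3 * se

    def test_event_class_frequencies_match_rates(self, rng):
        """Empirical event-class frequencies track the rate snapshot.

        With all five event classes active the realised counts over many
        steps must match the (state-dependent) rate proportions; we compare
        against the time-integrated expectation within 3 sigma.
        """
        p = SimulationParams(L=4, K=200.0, delta=0.1, beta=0.5, mu_d=0.01,
                             mu_b=0.01, k_in=0.3, k_out=0.5, gamma=0.4)
        pop = init_clonal(4, p, rng)
        engine = GillespieEngine(pop, p, rng)
        n_steps = 100_000
        expected = np.zeros(5)
        # accumulate expected class probabilities state by state
        for _ in range(n_steps):
            r = engine.rates()
            tot = r.grand_total
            expected += np.array([r.birth_total, r.death_total,
                                  r.switch_in_total, r.switch_out_total,
                                  r.recomb_total]) / tot
            if engine.step() is ABSORBED:
                pytest.fail("population unexpectedly absorbed")
        counts = np.array(engine.event_counts, dtype=float)
        for k in range(5):
            sd = math.sqrt(max(expected[k] * (1 - expected[k] / n_steps), 1.0))
            assert abs(counts[k] - expected[k]) < 4 * sd, (
                f"class {k}: {counts[k]} vs {expected[k]}"
            )


class TestMutation:
    def test_zero_rates_identity(self, rng):
        p = SimulationParams(L=8, K=10.0)
        g = np.array([1, 0, 1, 1, 0, 0, 1, 0], dtype=np.uint8)
        assert np.array_equal(mutate_genome(g, p, rng), g)

    def test_unit_rates_complement(self, rng):
        p = SimulationParams(L=8, K=10.0, mu_d=1.0, mu_b=1.0)
        g = np.array([1, 0, 1, 1, 0, 0, 1, 0], dtype=np.uint8)
        assert np.array_equal(mutate_genome(g, p, rng), 1 - g)

    def test_flip_counts_binomial(self, rng):
        """Flip counts on an all-ones genome follow Binomial(L, mu_d)."""
        L, mu = 10, 0.3
        p = SimulationParams(L=L, K=10.0, mu_d=mu)
        g = np.ones(L, dtype=np.uint8)
        n = 10_000
        flips = np.array([L - mutate_genome(g, p, rng).sum() for _ in range(n)])
        observed = np.bincount(flips, minlength=L + 1)
        expected = n * stats.binom.pmf(np.arange(L + 1), L, mu)
        keep = expected > 5
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        crit = stats.chi2.ppf(0.99, keep.sum() - 1)
        assert chi2 < crit

    def test_daughter_mutates_parent_untouched(self, rng):
        p = SimulationParams(L=6, K=1e9, mu_d=1.0)
        pop = make_pop(p, [Cell(Genome.from_bitstring("111111"))])
        engine = GillespieEngine(pop, p, rng)
        parent = pop.live_indices()[0]
        # keep stepping until a birth happens
        while engine.event_counts[int(EventType.BIRTH)] == 0:
            engine.step()
        assert pop.ones[parent] == 6          # parent never retro-mutated
        daughter = [i for i in pop.live_indices() if i != parent][0]
        assert pop.ones[daughter] == 0        # mu_d=1 forces all flips


class TestRecombination:
    def _competent_pop(self, params, bitstrings):
        return make_pop(params, [Cell(Genome.from_bitstring(b),
                                      Phenotype.COMPETENT)
                                 for b in bitstrings])

    def test_monomorphic_population_noop(self, rng):
        p = SimulationParams(L=4, K=1e9, gamma=5.0)
        pop = self._competent_pop(p, ["1010"] * 6)
        engine = GillespieEngine(pop, p, rng)
        for _ in range(2000):
            engine.step()
        # "null" exchanges only: per-locus frequencies are untouched
        np.testing.assert_allclose(pop.locus_one_frequencies(), [1, 0, 1, 0])

    def test_contaminated_pool_forces_zero(self, rng):
        p = SimulationParams(L=1, K=1e9, gamma=5.0, pool_lambda=1.0)
        pop = self._competent_pop(p, ["1"] * 4)
        engine = GillespieEngine(pop, p, rng)
        while engine.event_counts[int(EventType.RECOMBINATION)] < 20:
            engine.step()
        assert pop.mean_ones < 1.0   # ones get overwritten by pool zeros
        assert pop.total_ones < 4

    def test_recombination_frequency_matching(self):
        """Acceptor receives a one with probability = donor-pool frequency.

        K equals the census so the crowding factor zeroes the birth rate and
        the only possible event is a recombination.
        """
        p = SimulationParams(L=1, K=4.0, gamma=1.0, delta=0.0)
        got_one = 0
        n = 10_000
        master = np.random.default_rng(2024)
        for _ in range(n):
            pop = self._competent_pop(p, ["1", "0", "0", "0"])
            eng = GillespieEngine(pop, p, np.random.default_rng(
                int(master.integers(2 ** 31))))
            eng.step()  # the only possible event is one recombination
            # total ones increases iff a zero-cell acceptor received a one;
            # it decreases iff the one-cell accepted a zero
            if pop.total_ones == 2:
                got_one += 1
        # P(acceptor is a zero cell) * P(donor one) = (3/4) * (1/4)
        expect = 3 / 16
        se = math.sqrt(expect * (1 - expect) / n)
        assert abs(got_one / n - expect) < 3.5 * se


class TestRun:
    def test_zero_horizon_returns_initial_summary(self, rng, tri_population):
        engine = GillespieEngine(tri_population, rng=rng)
        res = engine.run(t_max=0.0)
        assert res.termination == "t_max"
        assert len(res.trajectory) == 2  # initial row + final row, no events
        assert res.trajectory.N[0] == 3

    def test_all_rates_zero_terminates_absorbed(self, rng):
        p = SimulationParams(L=2, K=10.0, delta=0.0)
        pop = make_pop(p, [Cell(Genome.from_bitstring("00"))])
        engine = GillespieEngine(pop, p, rng)
        res = engine.run(t_max=10.0)
        assert res.termination == "absorbed"

    def test_stationary_census_adiabatic(self, rng):
        """Monomorphic f=1, no other processes: N fluctuates around K(1-delta)."""
        p = SimulationParams(L=2, K=500.0, delta=0.1)
        pop = init_clonal(2, p, rng)
        engine = GillespieEngine(pop, p, rng)
        res = engine.run(t_max=400.0)
        assert res.time_avg_N == pytest.approx(450.0, rel=0.03)

    def test_event_cap_flags_truncation(self, rng):
        p = SimulationParams(L=2, K=100.0, delta=0.1)
        pop = init_clonal(2, p, rng)
        engine = GillespieEngine(pop, p, rng)
        res = engine.run(max_events=10)
        assert res.termination == "max_events" and res.truncated

    def test_determinism_identical_seeds(self):
        p = SimulationParams(L=10, K=80.0, delta=0.1, beta=0.5, mu_d=0.02,
                             mu_b=0.01, k_in=0.2, k_out=0.3, gamma=0.5, seed=42)
        trajs = []
        for _ in range(2):
            rng = np.random.default_rng(p.seed)
            pop = init_clonal(8, p, rng)
            engine = GillespieEngine(pop, p, rng)
            res = engine.run(max_events=5000, stride=1.0)
            trajs.append(res.trajectory)
        assert np.array_equal(trajs[0], trajs[1])

    def test_neutral_switching_fraction(self, rng):
        """Time-averaged competent fraction is k_in/(k_in+k_out).

        With beta=1, no recombination and no mutation, each cell is an
        independent two-state Markov chain, so the stationary competent
        probability follows from its master equation.
        """
        p = SimulationParams(L=2, K=150.0, delta=0.1, k_in=0.4, k_out=0.8)
        pop = init_clonal(2, p, rng)
        engine = GillespieEngine(pop, p, rng)
        engine.run(t_max=50.0)          # transient
        res = engine.run(t_max=1500.0)  # measurement
        expect = 0.4 / 1.2
        assert res.time_avg_pc == pytest.approx(expect, abs=0.02)

    def test_neutral_lineage_fixation_probability(self):
        """Labelling n0 of N identical cells fixes with probability n0/N."""
        p = SimulationParams(L=1, K=60.0, delta=0.2)
        n0 = 4
        fixed = 0
        reps = 600
        master = np.random.default_rng(7)
        N0 = None
        for _ in range(reps):
            rng = np.random.default_rng(int(master.integers(2 ** 31)))
            pop = init_clonal(1, p, rng)
            N0 = pop.N
            idx = rng.choice(pop.live_indices(), size=n0, replace=False)
            pop.lineage[idx] = 1
            engine = GillespieEngine(pop, p, rng)
            res = engine.run(stop_lineage=1, max_events=2_000_000)
            if res.termination == "lineage_fixed":
                fixed += 1
        expect = n0 / N0
        se = math.sqrt(expect * (1 - expect) / reps)
        assert abs(fixed / reps - expect) < 3 * se
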