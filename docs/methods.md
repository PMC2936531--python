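# Methods

## The model

`competence-evo` simulates a finite, well-mixed bacterial population in
continuous time. A chromosome is a vector of `L` binary loci; allele "1" is
the locally more fit family of sequences at that locus, allele "0" the less
fit one, and loci contribute independently to fitness (no epistasis). A
cell's intrinsic birth rate is the fraction of ones in its genome,
`f = ones / L`; crowding reduces the realised birth rate logistically,

    b = f · (1 − N/K),   floored at 0 for N ≥ K,

where `N` is the census and `K` the carrying capacity. Death occurs at a
constant rate `δ` per cell, independent of fitness, so birth and death are
decoupled (a logistic birth–death process rather than a Moran or
Wright–Fisher resampling scheme). Setting `dN/dt = 0` in the one-class
reduction gives the quasi-stationary census `N* = K(1 − δ/f)`, which the
simulation fluctuates around; every initializer founds the population at
this size so the census is initially neither growing nor shrinking.

Cells carry one of two phenotypes. *Vegetative* cells grow normally.
*Competent* cells do two things at once:

* they take up extracellular DNA: at rate `γ` per competent cell, the
  allele at one uniformly chosen locus is replaced by the homologous allele
  of a uniformly chosen living cell (the extracellular pool is assumed to
  mirror the living population's per-locus allele frequencies). The
  exchange is non-reciprocal — the displaced allele is degraded. With
  `pool_lambda > 0`, the donor allele is instead a "0" with that
  probability, modelling a pool loaded with deleterious alleles from
  preferentially lysed unfit cells;
* they are weak persisters: birth and death rates are both multiplied by a
  factor `β ∈ (0, 1]`. Because mutation happens at replication, the
  mutation rate is implicitly slowed by the same factor — the entire
  asexual dynamics of a competent cell runs `β` times slower. A persister
  is therefore competitively neutral in a stationary population but adapts
  more slowly.

Cells switch phenotype memorylessly: vegetative → competent at rate `k_in`,
back at rate `k_out`. When switching is selectively near-neutral the
competent fraction relaxes to `p_c = k_in / (k_in + k_out)`.

Mutation acts on the daughter genome at replication: each "1" flips with
probability `μ_d` per locus (deleterious), each "0" with probability `μ_b`
(beneficial, `μ_b < μ_d`), independently across loci, so several loci may
flip in one replication. The parent genome is never retro-mutated; which
copy mutates is a convention, chosen so that lineage bookkeeping can follow
a stable parent identity.

## Stochastic engine

Events are scheduled exactly with the Gillespie algorithm. The five event
classes and their aggregate rates over the population are

| event            | aggregate rate                                   |
|------------------|--------------------------------------------------|
| replication      | `(1 − N/K)·(Σ_veg f_i + β Σ_comp f_i)`           |
| death            | `δ·(#veg + β·#comp)`                             |
| switch in        | `Σ_veg k_in,i`                                   |
| switch out       | `Σ_comp k_out,i`                                 |
| recombination    | `γ·#comp`                                        |

Waiting times are exponential in the grand total; the event class is chosen
proportionally to its aggregate rate and the target cell by rejection
sampling inside its phenotype sector (envelope `L` for fitness-weighted
replication, the maximal per-cell rate for switching). Aggregate sums are
maintained incrementally in O(1) per event and re-derived from scratch
every 2^16 events (and after every event in debug mode, which also
recomputes every cache and asserts agreement at 1e-9 relative). Switching
rates are stored per cell so that strains with different switching
strategies — pure vegetative, fully committed competent, or stochastic
switchers — can compete within one population; lineage labels are copied
verbatim to offspring and never rewritten, which is what invasion
experiments count.

With a fixed seed the event sequence is bit-reproducible; replicate RNG
streams are spawned from a `SeedSequence` so results are independent of
replicate execution order.

The engine was validated against an independent brute-force reference: for
`L = 1` the whole population state is `(n_v0, n_v1, n_c0, n_c1)`, the full
generator over all states with `N ≤ K` is assembled explicitly, and its
quasi-stationary distribution (shift-invert eigensolve) is compared with
the time-weighted occupancy of a 10^6-event simulation. At the reference
condition (`K = 18`, all five event classes active) the total variation
distance is ≈ 0.015, at the finite-sample noise floor.

## Deterministic fitness-class model

Binning genotypes by their number of ones gives `L + 1` fitness classes
with vegetative and competent occupancies `n_j`, `m_j` at `x_j = j/L`. The
coupled system is

    dn/dt = (G + M) n − k_in n + k_out m
    dm/dt = β (G + M) m + R m + k_in n − k_out m

with, per class `j`:

* growth `G`: `[b_j θ(n_j − 1) − δ] n_j`, `b_j = x_j (1 − N/K)`. The
  Heaviside factor `θ` (occupancy ≥ 1 counts as on) shuts birth off in
  classes holding less than one cell — a heuristic stand-in for demographic
  noise that prevents fractional numbers of very fit cells from sweeping
  the dynamics. The cutoff gates *only* the net growth term; death acts on
  any occupancy (otherwise mass would be trapped), and the mutation flux
  uses the raw `b_j` (a sub-unity class keeps exchanging mutants with its
  neighbours).
* mutation `M`: nearest-neighbour fluxes, `μ_d · j · b_j n_j` down and
  `μ_b (L − j) · b_j n_j` up, proportional to the birth rate because
  mutation occurs at replication. Multiple simultaneous mutations are
  neglected here (not in the simulation). A `couple_to_birth=False` switch
  replaces `b_j` by a unit per-capita rate for sensitivity analysis; it is
  not the default because a per-time mutation flux overwhelms selection at
  the mutation rates used here and disagrees with the simulation's
  mutation-at-replication semantics.
* recombination `R` (competent sector only): assuming every genotype within
  a fitness class is uniformly represented — the maximal-diversity
  approximation — the donor allele is a "1" with probability
  `q = (1 − pool_lambda)·φ`, with `φ` the instantaneous population mean
  fraction of ones recomputed every step from the full `n + m` population.
  Per-cell move rates are `γ(1 − x_j)q` up and `γ x_j (1 − q)` down. Under
  `R` alone the sector mean obeys `d⟨x⟩/dt = γ(q − ⟨x⟩)/L` exactly, which
  the tests check against the closed form.

Mutation and recombination conserve total cell number to machine precision
by construction (flux form). Integration is explicit Euler with an enforced
step bound `dt · max_rate < 0.1`; the cutoff makes the right-hand side
discontinuous, so high-order smooth-ODE machinery would buy accuracy it
cannot use. Halving `dt` changes the final mean fitness by < 1e-6 relative
at the reference conditions. Negative occupancies produced by a discrete
step are clipped to zero and the clipped mass is accumulated and reported.

The no-drift equilibrium reference used by the equilibrium experiments is
this same solver run single-sector with the cutoff disabled — the classical
deterministic mutation–selection balance, including back mutation.

### Where the two solvers disagree

The fitness-class model overestimates the benefit of recombination because
the maximal-diversity assumption cannot be maintained by a finite
population; the overestimate is mild for shuffled (maximal-diversity)
initial conditions and large for clonal ones. At `γ = 0`, however, the
hard occupancy-1 cutoff makes the deterministic front a few percent
*slower* than the event-driven simulation across every desk-scale
configuration we examined — stochastic fronts outrun a deterministic
cutoff approximation (the Brunet–Derrida correction works in that
direction). So the deterministic solver bounds the simulation's adaptation
speed from above reliably only once recombination is appreciable; at
`γ ≈ 0` the two agree within a few percent, with no guaranteed ordering.

A related effect shows up at equilibrium: because selection acts on the
birth rate only (fecundity selection) and the recombination operator keeps
regenerating fitness variance, recombination raises the *deterministic*
no-drift balance itself, not just the finite-population one. The
equilibrium experiments therefore report the `γ = 0` no-drift balance as
their reference: simulated populations without recombination fall well
below it (drift load), and strongly recombining ones reach it and may
exceed it slightly.

## Experiment protocols

**Initial conditions.** `clonal`: every founder carries the identical
genome with `k1` ones. `shuffled`: each founder independently receives `k1`
ones at random distinct loci — the maximal genetic diversity compatible
with a fixed founder fitness. `natural`: a perfect clone is burned in to
mutation/selection/drift equilibrium, then the same `F` randomly chosen
loci are flipped in every cell, emulating a sudden environmental change
that displaces the population from its fitness peak while preserving the
standing diversity (a burn-in QC regresses mean ones on time over the final
quarter and requires slope p > 0.05).

**Velocity.** The adaptation speed is `v = (k_hi − k_lo) / Δt` with `Δt`
the interval between first upward crossings of the two thresholds by the
population mean number of ones. First crossing of the mean is a convention
(recorded per replicate); replicates that never reach `k_hi` are excluded
and counted. The per-generation variant divides the threshold gap by the
elapsed generations, defined as cumulative birth events divided by the
run's time-averaged census.

**Equilibrium.** Perfect-clone foundings run for `t_total`; the mean
fraction of ones is time-averaged over the final `window` and across
replicates, and reported next to the no-drift deterministic reference.

**Competitions.** Resident banks are saved populations — mid-climb
(adapting: founded clonal at `k_start`, saved at first crossing of
`k_save`) or equilibrated. Each competition copies a randomly chosen bank
member, relabels `n0` random cells as invaders (keeping their genomes:
invaders appear in sampled genetic backgrounds) and applies the invader's
competence strategy via per-cell switching rates. The run ends when the
invader lineage hits 0 or N; `p_fix` gets an exact binomial CI, the
expected descendants per invader is `p_fix / (n0/N̄)` (exactly 1 for a
neutral lineage), and `Ns = slope × N̄` from the least-squares line through
`p_fix(n0)`. The lack-of-fit chi-square of that line against the binomial
counts, plus a saturating `1 − (1 − r)^{n0}` alternative fitted by maximum
likelihood, is the frequency-dependence diagnostic. Replicates that hit the
protective event cap are censored: reported, never silently dropped.

**Competent-fraction sweep.** `p_c` is swept through `k_in` at fixed
`k_out`; each grid point measures `v` and the per-generation `v` for a
stochastically switching population. The deterministic solver supplies the
full curve cheaply; a stochastic confirmation with bootstrap resampling of
replicate velocities locates the argmax and its 90% interval.

## Reference study conditions

The frozen desk-scale conditions in `competence_evo.presets` are sized for
a single CPU (each block minutes, not hours):

* Engine-vs-chain check: `L=1, K=18, δ=0.1, β=0.6, μ_d=0.02, k_in=0.2,
  k_out=0.4, γ=0.5`, 10^6 events. `K` much below this lets the trajectory
  reach extinction within the run; broader rate choices spread occupancy
  over so many states that finite-sample noise alone exceeds the 0.02 TV
  margin.
* Switching balance: three `(k_in, k_out)` pairs at `K=200`, 1500 time
  units. Census balance: `K=500` at `f ∈ {1.0, 0.5}`.
* Neutral fixation: `L=1, K=200, δ=0.1` (census ≈ 180), `n0 ∈ {1, 5, 10}`,
  2000 replicates per point, exact 99% CIs.
* Velocity: `L=50, K=2000, δ=0.1, μ_d=0.01, μ_b=0.005` (genomic deleterious
  rate `U=0.5` — the many-concurrent-sweeps regime the model targets),
  all-competent `β=1`, shuffled founding at 12 ones, speeds measured
  between 15 and 23 ones, `γ ∈ {0, 0.3, 1, 4}`, 10 replicates. The large
  census keeps front-class occupancies near the cutoff representative.
* Equilibrium: `K=500`, `μ_d=0.01` with `μ_b=0.002` (a smaller
  beneficial-to-deleterious ratio than the velocity block, so back
  mutation contributes little to the balance), `γ ∈ {0, 2}`, 3000 time
  units with a 1000-unit averaging window.
* Sweep: `β=0.5, k_out=0.1`, `p_c` grid `{0.05, 0.25, 0.5, 0.75, 0.95}`,
  `γ ∈ {0, 4}` deterministic, with a three-point stochastic confirmation at
  `γ=4`.

What these conditions deliberately do not emulate: real genome sizes
(loci here stand for ~kilobase recombining segments, and mutation rates are
orders of magnitude above wild-type so that many beneficial mutations
segregate simultaneously in a census of a few hundred cells), density
dependence of transformation, environmental fluctuation, epistasis, and
explicit competence genes. Passing tests therefore show internal
consistency of the model and the direction and shape of its effects, not
quantitative predictions for laboratory populations.

## Numerical and degenerate-input choices

* Birth rates are floored at zero above carrying capacity; an empty
  population is a valid absorbing state (`ABSORBED` termination).
* Founders with `k1/L ≤ δ` are rejected (no stationary census exists).
* Tie-break: class occupancy exactly 1 counts as "on" for the cutoff.
* Incremental floating-point rate sums are resynchronised every 2^16
  events; cache drift tolerance 1e-9 relative.
* Uniform random numbers are consumed from a block buffer refilled from
  the generator; identical seeds give identical event sequences.
* Extinction during a burn-in raises an error carrying the trajectory.

## Known limitations

* The fitness-class solver is not a bound on the simulation at `γ ≈ 0`
  (see above); treat it as a fast qualitative map, trusting orderings
  rather than absolute speeds.
* Competition stopping uses absorbing states 0 and N for the invader
  lineage; long quasi-coexistence is cut by the event cap and reported as
  censoring rather than resolved.
* The natural-initialisation burn-in uses a fixed configured duration plus
  a trend QC, not an automated equilibrium detector.
* Performance: the engine executes 2–5 µs per event on one core, i.e.
  ~10^7–10^8 events per experiment block; census sizes beyond ~10^4 cells
  or genomes beyond a few hundred loci call for the deterministic solver
  instead.
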