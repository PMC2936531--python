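"""Core types: model parameters, genomes, cells, and the population container.

The model tracks a finite bacterial population in continuous time.  Each
chromosome is a vector of ``L`` binary loci: a "one" is the locally more fit
allele, a "zero" the less fit one.  A cell's intrinsic birth rate is the
fraction of ones in its genome (no epistasis), and crowding reduces the
actual birth rate logistically through a carrying capacity ``K``.  Cells are
either vegetative or competent; competent cells take up extracellular DNA
(homologous recombination) and express a weak persister phenotype in which
birth and death are both slowed by a common factor ``beta``.

The :class:`Population` container has multiset semantics over cells but is
internally a struct-of-arrays with cached aggregate sums so that the
stochastic engine can apply events in O(1) (plus O(L) genome copies).
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ParamError",
    "Phenotype",
    "SimulationParams",
    "Genome",
    "Cell",
    "Population",
    "PopulationSummary",
    "intrinsic_birth_rate",
    "actual_birth_rate",
    "population_summary",
]


class ParamError(ValueError):
    """Raised when a parameter value is outside its documented domain."""


class Phenotype(enum.IntEnum):
    VEGETATIVE = 0
    COMPETENT = 1


@dataclass(frozen=True)
class SimulationParams:
    """Full parameter vector shared by the stochastic and deterministic solvers.

    Parameters
    ----------
    L
        Number of genomic loci (bits).
    K
        Carrying capacity (cells).
    delta
        Vegetative death rate (1/time).
    beta
        Persister slow-down factor in (0, 1]: competent cells' birth, death
        and (through replication) mutation rates are ``beta`` times the
        vegetative rates.  ``beta=1`` degenerates to a pure-vegetative model.
    mu_d
        Deleterious (1 -> 0) mutation probability per locus per replication.
    mu_b
        Beneficial (0 -> 1) mutation probability per locus per replication.
    k_in, k_out
        Memory-less switching rates into / out of the competent phenotype
        (1/time).
    gamma
        Recombination rate per competent cell per time, genome wide.
    pool_lambda
        Fraction of the extracellular DNA pool consisting of all-"zero"
        (deleterious) alleles; 0 recovers a pool that exactly mirrors the
        living population.
    seed
        Default RNG seed for runs configured from this object.
    """

    L: int
    K: float
    delta: float = 0.1
    beta: float = 1.0
    mu_d: float = 0.0
    mu_b: float = 0.0
    k_in: float = 0.0
    k_out: float = 0.0
    gamma: float = 0.0
    pool_lambda: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.L, (int, np.integer)) or self.L < 1:
            raise ParamError(f"L must be a positive integer, got {self.L!r}")
        if not (self.K > 0):
            raise ParamError(f"K must be > 0, got {self.K!r}")
        if self.delta < 0:
            raise ParamError(f"delta must be >= 0, got {self.delta!r}")
        if not (0 < self.beta <= 1):
            raise ParamError(f"beta must be in (0, 1], got {self.beta!r}")
        for name in ("mu_d", "mu_b", "pool_lambda"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ParamError(f"{name} must be in [0, 1], got {v!r}")
        for name in ("k_in", "k_out", "gamma"):
            v = getattr(self, name)
            if v < 0:
                raise ParamError(f"{name} must be >= 0, got {v!r}")
        if not isinstance(self.seed, (int, np.integer)):
            raise ParamError(f"seed must be an integer, got {self.seed!r}")

    @property
    def U(self) -> float:
        """Total genomic deleterious mutation rate, ``L * mu_d`` (derived)."""
        return self.L * self.mu_d

    def replace(self, **changes) -> "SimulationParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        unknown = set(d) - set(cls.field_names())
        if unknown:
            raise ParamError(f"unknown parameter key(s): {sorted(unknown)}")
        missing = {"L", "K"} - set(d)
        if missing:
            raise ParamError(f"missing required parameter key(s): {sorted(missing)}")
        return cls(**d)


class Genome:
    """An ordered bit vector of ``L`` alleles with a popcount cache."""

    __slots__ = ("alleles",)

    def __init__(self, alleles) -> None:
        arr = np.asarray(alleles, dtype=np.uint8)
        if arr.ndim != 1:
            raise ValueError("alleles must be one-dimensional")
        if np.any(arr > 1):
            raise ValueError("alleles must be 0 or 1")
        self.alleles = arr

    @property
    def L(self) -> int:
        return self.alleles.shape[0]

    @property
    def ones(self) -> int:
        return int(self.alleles.sum())

    @classmethod
    def from_bitstring(cls, s: str) -> "Genome":
        return cls(np.frombuffer(s.encode(), dtype=np.uint8) - ord("0"))

    def bitstring(self) -> str:
        return "".join("1" if a else "0" for a in self.alleles)

    def __eq__(self, other) -> bool:
        return isinstance(other, Genome) and np.array_equal(self.alleles, other.alleles)

    def __hash__(self) -> int:
        return hash(self.alleles.tobytes())

    def __repr__(self) -> str:
        return f"Genome({self.bitstring()!r})"


@dataclass
class Cell:
    """A single cell: genome, phenotype, and an inherited lineage label.

    The lineage label is bookkeeping for invasion experiments: it is copied
    verbatim to offspring and never changed by any event.  ``k_in``/``k_out``
    may override the population-wide switching rates so that strains with
    different switching strategies can compete in one population.
    """

    genome: Genome
    phenotype: Phenotype = Phenotype.VEGETATIVE
    lineage: int = 0
    k_in: float | None = None
    k_out: float | None = None


def intrinsic_birth_rate(genome: Genome, L: int) -> float:
    """Intrinsic birth rate of a genome: the fraction of ones, ``ones / L``."""
    if genome.L != L:
        raise ValueError(f"genome has length {genome.L}, expected {L}")
    return genome.ones / L


def actual_birth_rate(f: float, N: float, K: float) -> float:
    """Logistic crowding: ``f * (1 - N/K)``, floored at zero above capacity."""
    if K <= 0:
        raise ParamError(f"K must be > 0, got {K!r}")
    return max(0.0, f * (1.0 - N / K))


@dataclass
class PopulationSummary:
    t: float
    N: int
    n_competent: int
    p_c: float
    mean_ones: float
    locus_one_freqs: np.ndarray


_VEG = int(Phenotype.VEGETATIVE)
_COMP = int(Phenotype.COMPETENT)


class Population:
    """Multiset of cells with clock, census, and cached aggregate rates.

    Cells live in fixed array slots; two per-phenotype index lists support
    O(1) uniform sampling within a phenotype sector, and the aggregate sums
    needed by the event rates (``sum of ones`` and switching-rate totals per
    sector) are maintained incrementally.  ``check_consistency`` recomputes
    everything from scratch and is called periodically by the engine (after
    every event in debug mode).
    """

    def __init__(self, params: SimulationParams, capacity: int | None = None) -> None:
        self.params = params
        self.L = params.L
        self.t = 0.0
        if capacity is None:
            # start modest and let _grow() double on demand: K can legally be
            # huge (an effectively unbounded population)
            capacity = min(int(math.ceil(params.K)) + 8, 4096)
        cap = max(capacity, 8)
        self._alloc(cap)
        # sector index lists: [vegetative, competent]
        self.sector: list[list[int]] = [[], []]
        # aggregate caches
        self.S_ones = [0, 0]          # sum of `ones` per sector
        self.S_kin = 0.0              # sum of per-cell k_in over vegetative cells
        self.S_kout = 0.0             # sum of per-cell k_out over competent cells
        self.max_kin = 0.0            # upper envelopes for rejection sampling
        self.max_kout = 0.0

    def _alloc(self, cap: int) -> None:
        self.capacity = cap
        self.genomes = np.zeros((cap, self.L), dtype=np.uint8)
        self.ones = np.zeros(cap, dtype=np.int64)
        self.phen = np.zeros(cap, dtype=np.uint8)
        self.lineage = np.zeros(cap, dtype=np.int64)
        self.kin = np.zeros(cap, dtype=np.float64)
        self.kout = np.zeros(cap, dtype=np.float64)
        self.alive = np.zeros(cap, dtype=bool)
        self._pos = np.zeros(cap, dtype=np.int64)   # position within sector list
        self._free = list(range(cap - 1, -1, -1))

    def _grow(self) -> None:
        old_cap = self.capacity
        cap = old_cap * 2
        for name in ("ones", "phen", "lineage", "kin", "kout", "alive", "_pos"):
            arr = getattr(self, name)
            new = np.zeros(cap, dtype=arr.dtype)
            new[:old_cap] = arr
            setattr(self, name, new)
        g = np.zeros((cap, self.L), dtype=np.uint8)
        g[:old_cap] = self.genomes
        self.genomes = g
        self._free.extend(range(cap - 1, old_cap - 1, -1))
        self.capacity = cap

    # -- census properties ------------------------------------------------

    @property
    def N(self) -> int:
        return len(self.sector[_VEG]) + len(self.sector[_COMP])

    @property
    def n_vegetative(self) -> int:
        return len(self.sector[_VEG])

    @property
    def n_competent(self) -> int:
        return len(self.sector[_COMP])

    @property
    def mean_ones(self) -> float:
        n = self.N
        return (self.S_ones[0] + self.S_ones[1]) / n if n else 0.0

    @property
    def total_ones(self) -> int:
        return self.S_ones[0] + self.S_ones[1]

    @property
    def competent_fraction(self) -> float:
        n = self.N
        return len(self.sector[_COMP]) / n if n else 0.0

    # -- mutation of the multiset -----------------------------------------

    def add_cell(self, alleles, phenotype, lineage: int = 0,
                 k_in: float | None = None, k_out: float | None = None) -> int:
        """Insert a cell and return its slot index."""
        if not self._free:
            self._grow()
        i = self._free.pop()
        row = np.asarray(alleles, dtype=np.uint8)
        if row.shape != (self.L,):
            raise ValueError(f"genome has shape {row.shape}, expected ({self.L},)")
        self.genomes[i] = row
        ones = int(row.sum())
        self.ones[i] = ones
        p = int(phenotype)
        self.phen[i] = p
        self.lineage[i] = lineage
        ki = self.params.k_in if k_in is None else k_in
        ko = self.params.k_out if k_out is None else k_out
        self.kin[i] = ki
        self.kout[i] = ko
        self.alive[i] = True
        lst = self.sector[p]
        self._pos[i] = len(lst)
        lst.append(i)
        self.S_ones[p] += ones
        if p == _VEG:
            self.S_kin += ki
        else:
            self.S_kout += ko
        if ki > self.max_kin:
            self.max_kin = ki
        if ko > self.max_kout:
            self.max_kout = ko
        return i

    def clone_add(self, row, ones, parent: int) -> int:
        """Fast path for replication: add a daughter of live cell ``parent``.

        ``row`` is the (already mutated) daughter genome and ``ones`` its
        popcount.  Phenotype, lineage and switching rates are copied from the
        parent, so the rejection-sampling envelopes are unchanged.
        """
        if not self._free:
            self._grow()
        i = self._free.pop()
        self.genomes[i] = row
        ones = int(ones)
        self.ones[i] = ones
        p = int(self.phen[parent])
        self.phen[i] = p
        self.lineage[i] = self.lineage[parent]
        ki = float(self.kin[parent])
        ko = float(self.kout[parent])
        self.kin[i] = ki
        self.kout[i] = ko
        self.alive[i] = True
        lst = self.sector[p]
        self._pos[i] = len(lst)
        lst.append(i)
        self.S_ones[p] += ones
        if p == _VEG:
            self.S_kin += ki
        else:
            self.S_kout += ko
        return i

    def remove_cell(self, i: int) -> None:
        if not self.alive[i]:
            raise ValueError(f"slot {i} is not alive")
        p = int(self.phen[i])
        lst = self.sector[p]
        pos = self._pos[i]
        last = lst[-1]
        lst[pos] = last
        self._pos[last] = pos
        lst.pop()
        self.S_ones[p] -= int(self.ones[i])
        if p == _VEG:
            self.S_kin -= float(self.kin[i])
        else:
            self.S_kout -= float(self.kout[i])
        self.alive[i] = False
        self._free.append(i)

    def set_phenotype(self, i: int, phenotype) -> None:
        p_old = int(self.phen[i])
        p_new = int(phenotype)
        if p_old == p_new:
            return
        lst = self.sector[p_old]
        pos = self._pos[i]
        last = lst[-1]
        lst[pos] = last
        self._pos[last] = pos
        lst.pop()
        new = self.sector[p_new]
        self._pos[i] = len(new)
        new.append(i)
        self.phen[i] = p_new
        ones = int(self.ones[i])
        self.S_ones[p_old] -= ones
        self.S_ones[p_new] += ones
        if p_old == _VEG:
            self.S_kin -= float(self.kin[i])
            self.S_kout += float(self.kout[i])
        else:
            self.S_kout -= float(self.kout[i])
            self.S_kin += float(self.kin[i])

    def set_allele(self, i: int, locus: int, allele: int) -> None:
        """Overwrite one allele (recombination); caches updated in O(1)."""
        old = int(self.genomes[i, locus])
        if old == allele:
            return
        self.genomes[i, locus] = allele
        d = 1 if allele else -1
        self.ones[i] += d
        self.S_ones[int(self.phen[i])] += d

    def set_genome(self, i: int, alleles) -> None:
        row = np.asarray(alleles, dtype=np.uint8)
        ones = int(row.sum())
        p = int(self.phen[i])
        self.S_ones[p] += ones - int(self.ones[i])
        self.genomes[i] = row
        self.ones[i] = ones

    def flip_loci_everywhere(self, loci) -> None:
        """Flip the allele at the given loci in every living cell."""
        idx = self.live_indices()
        sub = self.genomes[np.ix_(idx, loci)]
        self.genomes[np.ix_(idx, loci)] = 1 - sub
        self.ones[idx] = self.genomes[idx].sum(axis=1)
        for p in (_VEG, _COMP):
            s = self.sector[p]
            self.S_ones[p] = int(self.ones[s].sum()) if s else 0

    # -- views ------------------------------------------------------------

    def live_indices(self) -> np.ndarray:
        return np.fromiter(
            (i for p in (_VEG, _COMP) for i in self.sector[p]),
            dtype=np.int64, count=self.N,
        )

    def cells(self):
        """Iterate over live cells as :class:`Cell` objects (copies)."""
        for i in self.live_indices():
            yield Cell(
                genome=Genome(self.genomes[i].copy()),
                phenotype=Phenotype(int(self.phen[i])),
                lineage=int(self.lineage[i]),
                k_in=float(self.kin[i]),
                k_out=float(self.kout[i]),
            )

    @classmethod
    def from_cells(cls, params: SimulationParams, cells, t: float = 0.0) -> "Population":
        cells = list(cells)
        pop = cls(params, capacity=max(
            len(cells) + 8, min(int(math.ceil(params.K)) + 8, 4096)))
        pop.t = t
        for c in cells:
            if c.genome.L != params.L:
                raise ValueError(
                    f"cell genome length {c.genome.L} does not match L={params.L}"
                )
            pop.add_cell(c.genome.alleles, c.phenotype, c.lineage, c.k_in, c.k_out)
        return pop

    def copy(self) -> "Population":
        new = Population.__new__(Population)
        new.params = self.params
        new.L = self.L
        new.t = self.t
        new.capacity = self.capacity
        for name in ("genomes", "ones", "phen", "lineage", "kin", "kout",
                     "alive", "_pos"):
            setattr(new, name, getattr(self, name).copy())
        new._free = list(self._free)
        new.sector = [list(self.sector[0]), list(self.sector[1])]
        new.S_ones = list(self.S_ones)
        new.S_kin = self.S_kin
        new.S_kout = self.S_kout
        new.max_kin = self.max_kin
        new.max_kout = self.max_kout
        return new

    def lineage_count(self, lineage: int) -> int:
        idx = self.live_indices()
        return int(np.sum(self.lineage[idx] == lineage)) if idx.size else 0

    def locus_one_frequencies(self) -> np.ndarray:
        idx = self.live_indices()
        if idx.size == 0:
            return np.zeros(self.L)
        return self.genomes[idx].mean(axis=0)

    def summary(self) -> PopulationSummary:
        return PopulationSummary(
            t=self.t,
            N=self.N,
            n_competent=self.n_competent,
            p_c=self.competent_fraction,
            mean_ones=self.mean_ones,
            locus_one_freqs=self.locus_one_frequencies(),
        )

    # -- validation -------------------------------------------------------

    def check_consistency(self, rtol: float = 1e-9) -> None:
        """Recompute all caches from scratch and assert agreement."""
        for p in (_VEG, _COMP):
            for pos, i in enumerate(self.sector[p]):
                assert self.alive[i], f"dead slot {i} in sector {p}"
                assert int(self.phen[i]) == p
                assert self._pos[i] == pos
        idx = self.live_indices()
        assert len(set(idx.tolist())) == self.N, "duplicate slots in sectors"
        assert int(self.alive.sum()) == self.N
        for i in idx:
            assert int(self.ones[i]) == int(self.genomes[i].sum()), (
                f"ones cache stale at slot {i}"
            )
        for p in (_VEG, _COMP):
            s = self.sector[p]
            expect = int(self.ones[s].sum()) if s else 0
            assert self.S_ones[p] == expect, f"S_ones[{p}] cache drift"
        veg = self.sector[_VEG]
        comp = self.sector[_COMP]
        s_kin = float(self.kin[veg].sum()) if veg else 0.0
        s_kout = float(self.kout[comp].sum()) if comp else 0.0
        assert math.isclose(self.S_kin, s_kin, rel_tol=rtol, abs_tol=1e-12), (
            f"S_kin drift: {self.S_kin} vs {s_kin}"
        )
        assert math.isclose(self.S_kout, s_kout, rel_tol=rtol, abs_tol=1e-12), (
            f"S_kout drift: {self.S_kout} vs {s_kout}"
        )

    def resync_rate_caches(self) -> None:
        """Recompute the floating-point switching-rate sums (drift control)."""
        veg = self.sector[_VEG]
        comp = self.sector[_COMP]
        self.S_kin = float(self.kin[veg].sum()) if veg else 0.0
        self.S_kout = float(self.kout[comp].sum()) if comp else 0.0

    def __repr__(self) -> str:
        return (f"Population(N={self.N}, n_competent={self.n_competent}, "
                f"mean_ones={self.mean_ones:.3f}, t={self.t:.3f})")


def population_summary(pop: Population) -> PopulationSummary:
    """Summary record: census, competent fraction, mean ones, per-locus freqs."""
    return pop.summary()
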