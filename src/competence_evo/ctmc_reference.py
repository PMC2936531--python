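"""Brute-force continuous-time Markov-chain reference for the L=1 model.

For a single locus the population state is fully described by the four
counts ``(n_v0, n_v1, n_c0, n_c1)`` — vegetative/competent cells carrying
the zero/one allele.  For small carrying capacities the entire state space
can be enumerated and the generator assembled explicitly, giving an
independent check of the event-driven engine: the engine's time-averaged
occupancy over a long run must match the chain's quasi-stationary
distribution (extinction is absorbing but astronomically slow at the
parameters of interest, so the QSD is what a long trajectory samples).

This module shares no code with the engine: rates are rebuilt from the
model definition and the stationary behaviour comes from a sparse
eigensolve, not from simulation.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .core import SimulationParams

__all__ = [
    "enumerate_states",
    "build_generator",
    "quasi_stationary_distribution",
    "total_variation",
]

State = tuple[int, int, int, int]  # (n_v0, n_v1, n_c0, n_c1)


def enumerate_states(n_max: int) -> list[State]:
    """All states with ``1 <= N <= n_max`` (extinction excluded)."""
    states = []
    for total in range(1, n_max + 1):
        for a in range(total + 1):
            for b in range(total - a + 1):
                for c in range(total - a - b + 1):
                    d = total - a - b - c
                    states.append((a, b, c, d))
    return states


def _transitions(s: State, p: SimulationParams, n_max: int):
    """Yield ``(rate, target_state)`` pairs; targets with N > n_max are invalid."""
    nv0, nv1, nc0, nc1 = s
    N = nv0 + nv1 + nc0 + nc1
    crowd = max(0.0, 1.0 - N / p.K)
    ones = nv1 + nc1

    # replication (only allele-1 cells have a non-zero intrinsic rate at L=1);
    # the daughter may carry a deleterious mutation
    if crowd > 0.0 and N < n_max:
        b_v = nv1 * crowd
        if b_v > 0:
            yield b_v * (1.0 - p.mu_d), (nv0, nv1 + 1, nc0, nc1)
            if p.mu_d > 0:
                yield b_v * p.mu_d, (nv0 + 1, nv1, nc0, nc1)
        b_c = p.beta * nc1 * crowd
        if b_c > 0:
            yield b_c * (1.0 - p.mu_d), (nv0, nv1, nc0, nc1 + 1)
            if p.mu_d > 0:
                yield b_c * p.mu_d, (nv0, nv1, nc0 + 1, nc1)

    # death
    if nv0:
        yield p.delta * nv0, (nv0 - 1, nv1, nc0, nc1)
    if nv1:
        yield p.delta * nv1, (nv0, nv1 - 1, nc0, nc1)
    if nc0:
        yield p.beta * p.delta * nc0, (nv0, nv1, nc0 - 1, nc1)
    if nc1:
        yield p.beta * p.delta * nc1, (nv0, nv1, nc0, nc1 - 1)

    # switching
    if p.k_in:
        if nv0:
            yield p.k_in * nv0, (nv0 - 1, nv1, nc0 + 1, nc1)
        if nv1:
            yield p.k_in * nv1, (nv0, nv1 - 1, nc0, nc1 + 1)
    if p.k_out:
        if nc0:
            yield p.k_out * nc0, (nv0 + 1, nv1, nc0 - 1, nc1)
        if nc1:
            yield p.k_out * nc1, (nv0, nv1 + 1, nc0, nc1 - 1)

    # recombination: the donor allele is drawn from the living population
    # (acceptor included), contaminated by all-zero DNA with prob pool_lambda
    if p.gamma:
        q = (1.0 - p.pool_lambda) * ones / N
        if nc0 and q > 0:
            yield p.gamma * nc0 * q, (nv0, nv1, nc0 - 1, nc1 + 1)
        if nc1 and q < 1:
            yield p.gamma * nc1 * (1.0 - q), (nv0, nv1, nc0 + 1, nc1 - 1)


def build_generator(params: SimulationParams, n_max: int
                    ) -> tuple[sp.csr_matrix, dict[State, int]]:
    """Sparse generator over the non-extinct states.

    Row sums are ``-(rate into extinction)`` for states that can go extinct
    and zero otherwise; transitions that would exceed ``n_max`` cells cannot
    occur (birth is rate-zero at the capacity boundary when ``n_max >= K``).
    """
    if params.L != 1:
        raise ValueError("the brute-force reference is built for L = 1")
    states = enumerate_states(n_max)
    index = {s: i for i, s in enumerate(states)}
    rows, cols, vals = [], [], []
    for s, i in index.items():
        out = 0.0
        for rate, tgt in _transitions(s, params, n_max):
            if rate <= 0.0:
                continue
            out += rate
            j = index.get(tgt)
            if j is not None:  # extinction transitions leave the space
                rows.append(i)
                cols.append(j)
                vals.append(rate)
        rows.append(i)
        cols.append(i)
        vals.append(-out)
    n = len(states)
    Q = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return Q, index


def quasi_stationary_distribution(params: SimulationParams, n_max: int
                                  ) -> dict[State, float]:
    """QSD: the left eigenvector of the restricted generator nearest zero."""
    Q, index = build_generator(params, n_max)
    # shift-invert around 0: the restricted generator is non-singular because
    # every state eventually reaches extinction
    vals, vecs = spla.eigs(Q.T.tocsc(), k=1, sigma=0.0)
    v = np.real(vecs[:, 0])
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    v /= v.sum()
    return {s: float(v[i]) for s, i in index.items()}


def total_variation(p: dict, q: dict) -> float:
    keys = set(p) | set(q)
    return 0.5 * sum(abs(p.get(k, 0.0) - q.get(k, 0.0)) for k in keys)
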