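"""Desk-scale study configurations.

These are the package's reference conditions for validation and for the
reproduction script: small enough to run on one CPU in minutes, large
enough that every qualitative regime of the model (drift, clonal
interference, recombination benefit, persister cost) is expressed.  The
choices are documented in the methods note; they are deliberately frozen
here so that tests, scripts and documentation all speak about the same
numbers.
"""

from __future__ import annotations

from .core import SimulationParams

# -- tiny single-locus system for the brute-force Markov-chain cross-check --
ORACLE = dict(
    params=SimulationParams(L=1, K=18.0, delta=0.1, beta=0.6, mu_d=0.02,
                            k_in=0.2, k_out=0.4, gamma=0.5),
    n_events=1_000_000,
)

# -- neutral switching: competent fraction vs switching rates ---------------
SWITCHING_PAIRS = [(0.3, 0.6), (0.1, 0.4), (0.5, 0.25)]
SWITCHING = dict(L=2, K=200.0, delta=0.1, beta=1.0)
SWITCHING_T = 1500.0

# -- stationary census: time-averaged N vs the adiabatic prediction ---------
CENSUS_SETTINGS = [
    dict(k1=2, L=2, K=500.0, delta=0.1),    # f = 1.0 -> N* = 450
    dict(k1=1, L=2, K=500.0, delta=0.2),    # f = 0.5 -> N* = 300
]
CENSUS_T = 600.0

# -- neutral invasions: fixation probability of exchangeable labels ---------
FIXATION = dict(
    params=SimulationParams(L=1, K=200.0, delta=0.1),
    n0_list=[1, 5, 10],
    replicates=2000,
)

# -- adaptation velocity vs recombination rate ------------------------------
# Large census keeps the deterministic noise cutoff representative of the
# front classes; the window sits well below mutation-selection balance.
VELOCITY = dict(
    base=dict(L=50, K=2000.0, delta=0.1, mu_d=0.01, mu_b=0.005),
    gamma_grid=[0.0, 0.3, 1.0, 4.0],
    k1=12, k_lo=15, k_hi=23,
    replicates=10,
    t_cap=8000.0,
)

# -- equilibrium fitness vs recombination rate ------------------------------
# mu_b/mu_d = 0.2 keeps the back-mutation contribution to the balance small
# so the no-drift reference is a meaningful ceiling for the recombining runs
EQUILIBRIUM = dict(
    base=dict(L=50, K=500.0, delta=0.1, mu_d=0.01, mu_b=0.002),
    gamma_strong=2.0,
    t_total=3000.0, window=1000.0,
    replicates=4,
)

# -- optimal competent fraction (switching sweep) ---------------------------
SWEEP = dict(
    base=dict(L=50, K=500.0, delta=0.1, mu_d=0.01, mu_b=0.005, beta=0.5),
    k_out=0.1,
    pc_grid=[0.05, 0.25, 0.5, 0.75, 0.95],
    gamma_strong=4.0,
    k1=12, k_lo=15, k_hi=23,
    stoch_pc_points=[0.05, 0.5, 0.95],
    stoch_replicates=6,
    t_cap=20000.0,
)


def kin_for_pc(p_c: float, k_out: float) -> float:
    """Switching-in rate that yields competent fraction ``p_c`` at fixed k_out."""
    return k_out * p_c / (1.0 - p_c)
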