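# One stochastic trajectory: perfect clone at carrying capacity with
# mutation, switching and recombination all active.
L: 50
K: 500.0
delta: 0.1
beta: 0.5
mu_d: 0.01
mu_b: 0.005
k_in: 0.1
k_out: 0.1
gamma: 1.0
seed: 1
t_max: 500.0
stride: 5.0
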