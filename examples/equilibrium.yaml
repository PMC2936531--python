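# Equilibrium fitness from perfect-clone foundings, strong recombination.
L: 50
K: 500.0
delta: 0.1
mu_d: 0.01
mu_b: 0.005
gamma: 2.0
seed: 1
t_total: 3000.0
window: 1000.0
replicates: 4
phenotype_policy: competent
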