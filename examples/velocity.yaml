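# Adaptation-speed measurement for a fully competent population (beta = 1
# so persistence is off; recombination on).
L: 50
K: 2000.0
delta: 0.1
mu_d: 0.01
mu_b: 0.005
gamma: 4.0
seed: 1
k1: 12
k_lo: 15
k_hi: 23
replicates: 6
t_max: 8000.0
phenotype_policy: competent
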