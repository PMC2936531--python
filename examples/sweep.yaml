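# Competent-fraction sweep: switching population with a persister cost.
L: 50
K: 500.0
delta: 0.1
beta: 0.5
mu_d: 0.01
mu_b: 0.005
gamma: 4.0
k_out: 0.1
seed: 1
k1: 12
k_lo: 15
k_hi: 23
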