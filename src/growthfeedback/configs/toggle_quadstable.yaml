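kind: toggle
k0_1: 0.001
k0_2: 0.001
k1_1: 0.2
k1_2: 0.2
K_1: 3.0
K_2: 3.0
n_1: 2.0
n_2: 2.0
d0_1: 0.01
d0_2: 0.01
J: 1.0
kg0: 0.95
m: 2.0
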