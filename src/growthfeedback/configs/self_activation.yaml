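kind: self_activation
k0: 0.002
k1: 0.36
K: 0.1
n: 2.0
d0: 0.02
J: 1.0
kg0: 1.0
m: 2.0
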