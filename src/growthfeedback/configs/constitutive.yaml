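kind: constitutive
k0: 0.1
d0: 0.0015
J: 1.0
kg0: 0.9
m: 2.0
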