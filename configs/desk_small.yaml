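# Desk-scale run: small comb in a 12-sigma box, minutes on one CPU.
Lb: 8
La: 2
Na: 4
L: 12
gamma_dot: 0.2
warmup: 30.0
production: 150.0
seed: 1
obs_stride: 2
frame_stride: 10
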