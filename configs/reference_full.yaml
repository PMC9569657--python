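# Cluster-scale reference conditions: dense comb (Lb = La = 20, one arm per
# backbone bead, N = 420 beads) in an L = 100 sigma box (~10^7 solvent
# particles). Long multi-shear-rate sweeps at this size are required for the
# quantitative scaling exponents (Gxx ~ gamma_dot^0.11, mG ~ Wi^0.70/0.78,
# [eta] ~ Wi^0.25, tau_eq ~ La^1.55); run with
#   combflow sweep configs/reference_full.yaml --gamma-dot 0.001 0.003 0.01 0.03 0.1 0.3
Lb: 20
La: 20
L: 100
gamma_dot: 0.01
warmup: 2000.0
production: 20000.0
seed: 1
obs_stride: 5
frame_stride: 100
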