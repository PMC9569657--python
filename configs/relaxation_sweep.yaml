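# Equilibrium relaxation-time sweep (cluster scale): run at gamma_dot = 0 for
# La in {5, 10, 20, 40}, fit the arm end-to-end autocorrelation to
# C0 exp(-t/tau_eq), then fit tau_eq vs La to a power law (expected exponent
# ~1.55). Edit La per run.
Lb: 20
La: 10
L: 100
gamma_dot: 0.0
warmup: 2000.0
production: 50000.0
seed: 1
obs_stride: 10
frame_stride: 200
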