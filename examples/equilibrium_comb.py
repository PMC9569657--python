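"""Equilibrium shape of a small comb polymer in a quiescent MPCD solvent.

Runs a few short, independently seeded hybrid MD+MPCD simulations of a
6-bead backbone with three 2-bead arms at zero shear and prints the
ensemble-averaged gyration tensor diagonal. Without flow the three
components agree within the run-to-run standard error: lab-frame shape
components decorrelate on the slow rotational-diffusion time, so averaging
over independent runs — not within one short trajectory — is what shows the
isotropy.
"""

import numpy as np

from combflow import RunConfig, run_simulation

runs = []
for seed in (700, 701, 702, 703):
    cfg = RunConfig(Lb=6, La=2, Na=3, L=8, gamma_dot=0.0,
                    warmup=30.0, production=150.0, seed=seed, obs_stride=5)
    df = run_simulation(cfg).observables
    runs.append([df.Gxx.mean(), df.Gyy.mean(), df.Gzz.mean(), df.RG2.mean()])
a = np.array(runs)
m, se = a.mean(axis=0), a.std(axis=0, ddof=1) / np.sqrt(len(a))
print(f"comb Lb=6, La=2, Na=3 (12 beads), gamma_dot=0, {len(runs)} runs")
print(f"<Gxx> = {m[0]:.2f}+-{se[0]:.2f}  <Gyy> = {m[1]:.2f}+-{se[1]:.2f}  "
      f"<Gzz> = {m[2]:.2f}+-{se[2]:.2f}  (sigma^2)")
print(f"<RG2> = {m[3]:.2f}+-{se[3]:.2f}; components agree within error: "
      "no preferred direction at equilibrium")
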