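"""Solvent viscosity: kinetic theory vs a sheared-fluid measurement.

Evaluates the SRD kinetic-theory closed form at the liquid-like parameter
point (alpha = 130 deg, h = 0.1 tau, 10 particles per cell) and then measures
the same viscosity from the momentum flux through the mid-plane of a small
Lees-Edwards Couette simulation. The two numbers should agree within a few
percent; both are in MPCD units sqrt(m kBT)/a^2.
"""

from combflow import FluidParams, kinetic_theory_viscosity, run_fluid

params = FluidParams(gamma_dot=0.05)
eta_kin, eta_coll = kinetic_theory_viscosity(params, parts=True)
print(f"kinetic-theory viscosity : {eta_kin + eta_coll:.3f} "
      f"(kinetic {eta_kin:.3f} + collisional {eta_coll:.3f})")

res = run_fluid(params, n_side=10, n_steps=2000, seed=1, warmup=400)
print(f"measured in Couette flow : {res.viscosity:.3f} "
      f"({res.n_particles} particles, 2000 collision steps)")
print(f"fitted profile slope     : {res.profile.slope:.4f} "
      f"(configured shear rate {params.gamma_dot})")
print(f"fluid temperature        : {res.kBT:.4f} (thermostat target 1.0)")
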