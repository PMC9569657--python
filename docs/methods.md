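# Methods

## Model and units

All quantities are in MPCD units: solvent mass m, cell edge a, thermal
energy k_BT, time τ = √(m a²/k_BT). The bead-spring comb uses the WCA
excluded-volume potential between **all** bead pairs (the standard
Kremer–Grest choice; applying it only to non-bonded pairs would leave the
bare FENE spring with its minimum at r = 0 and allow bond crossing) and a
FENE spring on bonds. With K = 30 ε/σ² and l0 = 1.5 σ the combined bond
potential has a single steep minimum at r ≈ 0.961 σ, so bonds cannot cross.
The WCA energy is shifted by +ε inside the cutoff by default so it is
continuous at 2^(1/6) σ; an unshifted variant is available
(`ModelParams(shift_wca=False)`) — the shift changes no force.

Grafting: `Na = Lb` (one arm per backbone bead) is the default dense comb;
for `Na < Lb` arms sit at the evenly spaced backbone indices
round(k(Lb−1)/(Na−1)). `La = 0` or `Na = 0` gives the bare backbone, which
is the linear-chain reference throughout.

## SRD solvent and coupling

Streaming advances positions ballistically over the collision time h;
collisions rotate velocities relative to the mass-weighted cell average by
α about one uniformly random axis per cell per step. Cells with fewer than
two members are skipped. A uniform grid shift in [−a/2, a/2]³ precedes every
collision (Galilean invariance). Under Lees–Edwards boundary conditions a
particle imaged through the z-boundary — by streaming or by the grid shift —
has its x-coordinate shifted by the accumulated offset (γ̇ L t mod L) and
participates in its cell's collision with vx boosted by ±γ̇L, with the boost
removed afterwards; this keeps sheared boundary cells consistent.

Thermostat: the named "Maxwell–Boltzmann thermostat" is implemented as
Maxwell–Boltzmann scaling (MBS): each cell's relative kinetic energy is
redrawn from the canonical Gamma distribution with 3(N_c − 1) degrees of
freedom and the relative velocities rescaled to it. MBS is the default
because it samples the canonical ensemble exactly — equilibrium velocity
marginals pass a Kolmogorov–Smirnov test at the 1% level on 10⁵ samples —
whereas a plain per-cell rescale (`thermostat="rescale"`, also provided)
pins each cell's instantaneous temperature and distorts fluctuations. Both
leave the cell centre-of-mass velocity untouched, so momentum is conserved
exactly. The thermostat acts on all cell members, monomers included.

The hybrid step runs h/hp = 20 velocity-Verlet substeps for the polymer
(solvent frozen), streams the solvent once, then performs the joint
collision in which monomers enter the cell average with mass M = 10 m.
There are no solvent–monomer pair forces; collisional coupling alone
thermalizes the chain (monomer kinetic temperature equilibrates to the
fluid's within the tests' 5% tolerance).

## Viscosity measurement

The closed-form SRD viscosity η = ρ(ν_kin + ν_coll) uses the standard
molecular-chaos expressions with fluctuating cell occupancy at mean density
M per cell; at α = 130°, h = 0.1, ⟨N_cs⟩ = 10 it gives 8.700 √(m k_BT)/a²
(the conventional unit; the equivalent form m k_BT/a⁴ multiplied by τ is
sometimes printed). The simulated cross-check measures the x-momentum flux
through the plane z = L/2 of a Couette run: streaming crossings carry
m·vx·sign(vz), and the collision+thermostat momentum change of all particles
above the plane captures the collisional transfer (cells imaged through the
sheared boundary are excluded — they transfer momentum through the boundary,
not the mid-plane). η = −⟨flux⟩/γ̇. At γ̇ = 0.05 in a 16³ box, ~2500
measured steps give η within a few percent of theory.

## Estimators

* **Tumbling fit.** ω is initialized at the dominant discrete-Fourier peak
  of the mean-subtracted cos θ_back series (deterministic, reproducible) and
  refined by bounded nonlinear least squares; a fit whose spectral peak is
  below 6× the median spectral amplitude is flagged unconverged instead of
  raising. The ensemble tumbling frequency is the mean of converged ω across
  runs; a zero-crossing counter is provided as a model-free cross-check.
* **Relaxation fit.** C(t) is the FFT-based autocorrelation of end-to-end
  vectors averaged over time origins and arms, normalized to C(0) = 1, fit
  to C0·exp(−t/τ_eq) on the window where C > 0.05. For the bare backbone
  (no arms) the backbone's own autocorrelation defines τ_eq and hence Wi.
* **Alignment.** χ_G = ½ atan2(2G_xz, G_xx − G_zz), which handles the
  G_xx = G_zz limit (χ_G → π/4 for positive G_xz) without a division.
* **Intrinsic viscosity.** The two dissipation channels (flow perturbation
  and rotational friction) are not separable from the published definition;
  their sum is taken as the steady-state identity ẇ1 + ẇ2 = γ̇·σ_xz per
  unit volume, with σ_xz = −(1/V) Σ_pairs F_x r_z the chain's Kramers virial
  stress, giving [η] = σ_xz V/(η0 γ̇ N) in σ³ per bead.
* **"Fully stretched" backbone length** is operationalized as the mean of
  the top 1% of |R_ete,back| samples (quantile configurable); whether the
  reference analyses used per-cycle maxima or a global quantile is not
  determinable, and the choice only shifts the curve, not its trends.

## Synthetic fixtures

The fixture module generates inputs with stored ground truth: rigid-rotor
orientation series (known ω), exponentially decaying correlations (known τ),
point clouds with closed-form gyration tensors, ideal Gaussian chains
(⟨R²⟩ = (N−1)b²) and thermalized solvent states. Noise is additive Gaussian.
These validate every estimator independently of the simulator; they do not
emulate hydrodynamic correlations, finite-box effects or shear-rate-dependent
conformational statistics, so estimator tests passing on fixtures shows the
estimators are unbiased, not that a small simulation reaches the asymptotic
scaling regimes.

## Problem sizes and what the tests show

Desk-scale study conditions, chosen once: Couette viscosity in a 16³-cell
box (≈41k particles, ~3000 collision steps); equilibrium-isotropy and
shear-response runs of an Lb = 6, La = 2, Na = 3 comb in L = 8–10 σ boxes,
averaged over independent seeds (lab-frame gyration components decorrelate
on the chain's rotational-diffusion time, ~10² τ at η ≈ 8.7, and are
anticorrelated within one trajectory, so statistics use per-run means of
independent runs and standard errors of per-run differences); the tumbling
check uses an Lb = 20, La = 4, Na = 10 comb in an L = 20 σ box at γ̇ = 0.5.
At these sizes the suite verifies conservation laws, equipartition, the
linear Couette profile, viscosity against kinetic theory, estimator
recovery, and the qualitative structural response (G_xx growing with γ̇,
G_xz > 0, end-over-end tumbling with sign-changing cos θ_back). The
quantitative scaling exponents (G_xx ∼ γ̇^0.11, R_G² ∼ γ̇^0.12–0.18,
tan 2χ_G ∼ γ̇^−0.23–−0.38, m_G ∼ Wi^0.70–0.78, [η] ∼ Wi^0.25,
τ_eq ∼ La^1.55) require L = 100 σ boxes (~10⁷ solvent particles) and long
multi-γ̇ sweeps; cluster-ready configs for those conditions are under
`configs/`. A stretched Lb = 20 backbone (up to ~28 σ with stressed bonds)
overlaps its own periodic image in boxes below ~30 σ, which perturbs
absolute shape statistics at the tumbling-test scale but not the sign/cycle
structure it asserts.

## Numerical choices and edge cases

* Single master seed per run; solvent init, polymer growth and dynamics use
  independent spawned substreams, so runs are bit-reproducible.
* Initial configurations grow self-avoidingly (bond 0.97 σ, non-bonded
  clearance ≥ 0.85 σ) with backtracking and bounded restarts, then relax
  under force-capped damped MD before coupling; a box too small raises a
  placement error rather than looping.
* A bond reaching l0 raises `BrokenBondError` naming the bond; non-finite
  coordinates raise `IntegrationError` naming the collision step.
* Fit tolerances: curve fits run with xtol 1e-12 and at most 10⁴
  evaluations; power-law fits are ordinary least squares in log-log space.
* Degenerate inputs are legal where physically meaningful: single-bead
  chains have zero end-to-end vector, La = 0 combs are bare backbones,
  cells containing only monomers collide with the monomer-only average.

## Known limitations

No angular-momentum-conserving collision variant, no walls, no entanglement
analysis, no eigenvalue shape parameters beyond the gyration tensor, no
block-bootstrap error bars (plain standard errors only), and single-threaded
execution only. The kinetic-theory viscosity is itself a molecular-chaos
approximation, accurate to a few percent at the reference parameters —
consistent with the level of agreement the Couette measurement shows.
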