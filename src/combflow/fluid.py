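"""SRD solvent: streaming, stochastic rotation collisions, thermostat, shear.

Multi-particle collision dynamics (stochastic rotation dynamics variant): the
solvent is a gas of point particles that stream ballistically for a collision
time ``h`` and are then sorted into cubic cells of edge ``a``, where their
velocities relative to the cell's centre-of-mass velocity are rotated by a
fixed angle ``alpha`` about a random axis (one axis per cell per step). Mass,
momentum and (pre-thermostat) energy are conserved cell-wise, which is enough
for hydrodynamics to emerge on scales beyond the cell size. A random grid
shift before every collision restores Galilean invariance, Lees-Edwards
images drive a linear shear profile v = gamma_dot * z * x_hat, and a
cell-level Maxwell-Boltzmann thermostat removes the viscous heat.

Monomers of an embedded polymer participate in the collision step with their
own mass M, which is the only solvent-polymer coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .box import ShearBox
from .errors import CombflowError

__all__ = [
    "FluidParams",
    "SolventState",
    "CellDecomposition",
    "initialize_solvent",
    "stream",
    "random_rotation_matrix",
    "grid_shift_and_sort",
    "collide",
    "cell_thermostat",
    "relative_kinetic_temperature",
    "kinetic_theory_viscosity",
    "measure_velocity_profile",
    "run_fluid",
]


@dataclass(frozen=True)
class FluidParams:
    """SRD solvent parameters in MPCD units (a = sigma, m = kBT = 1 default).

    ``h`` is the collision time in tau = sqrt(m a^2 / kBT), ``alpha`` the
    rotation angle in degrees, ``mean_density`` the average particle number
    per collision cell, ``gamma_dot`` the imposed shear rate in 1/tau.
    ``thermostat`` selects 'mbs' (Maxwell-Boltzmann scaling, canonical),
    'rescale' (exact per-cell rescale) or 'none'.
    """

    h: float = 0.1
    a: float = 1.0
    alpha: float = 130.0
    mean_density: float = 10.0
    solvent_mass: float = 1.0
    kBT: float = 1.0
    gamma_dot: float = 0.0
    thermostat: str = "mbs"

    def __post_init__(self):
        if self.h <= 0 or self.a <= 0:
            raise ValueError("FluidParams: h and a must be positive")
        if not 0.0 <= self.alpha <= 180.0:
            raise ValueError("FluidParams: alpha must lie in [0, 180] degrees")
        if self.mean_density < 1:
            raise ValueError("FluidParams: mean_density must be >= 1")
        if self.thermostat not in ("mbs", "rescale", "none"):
            raise ValueError(f"FluidParams: unknown thermostat {self.thermostat!r}")


@dataclass
class SolventState:
    """Phase space of the solvent plus the box geometry it lives in."""

    positions: np.ndarray
    velocities: np.ndarray
    L: float
    shear_offset: float = 0.0

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def box(self) -> ShearBox:
        return ShearBox(self.L, self.shear_offset)

    def advance_offset(self, dt: float, gamma_dot: float) -> None:
        self.shear_offset = float(
            np.mod(self.shear_offset + gamma_dot * self.L * dt, self.L)
        )


def initialize_solvent(
    L: float,
    params: FluidParams,
    rng: np.random.Generator,
    linear_profile: bool = False,
) -> SolventState:
    """Thermalized solvent: uniform positions, Maxwellian velocities at kBT,
    zero net momentum; optionally superimpose the steady Couette profile
    vx = gamma_dot * (z - L/2) so shear measurements start near steady state.
    """
    n_side = int(round(L / params.a))
    ns = int(round(params.mean_density * n_side**3))
    pos = rng.uniform(0.0, L, size=(ns, 3))
    vel = rng.normal(scale=np.sqrt(params.kBT / params.solvent_mass), size=(ns, 3))
    vel -= vel.mean(axis=0)
    if linear_profile:
        vel[:, 0] += params.gamma_dot * (pos[:, 2] - L / 2.0)
    return SolventState(positions=pos, velocities=vel, L=L)


def stream(state: SolventState, h: float, gamma_dot: float = 0.0) -> SolventState:
    """Ballistic streaming r -> r + v h, then Lees-Edwards wrapping (in place).

    The accumulated boundary offset is advanced by gamma_dot*L*h before
    wrapping, so crossings use the offset at the end of the interval.
    """
    state.positions += state.velocities * h
    state.advance_offset(h, gamma_dot)
    state.box.wrap(state.positions, state.velocities, gamma_dot)
    return state


def random_rotation_matrix(alpha: float, rng: np.random.Generator) -> np.ndarray:
    """Rotation by ``alpha`` degrees about an axis uniform on the unit sphere.

    Orthogonal with determinant 1 and trace 1 + 2 cos(alpha).
    """
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    th = np.deg2rad(alpha)
    c, s = np.cos(th), np.sin(th)
    ux = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return c * np.eye(3) + s * ux + (1 - c) * np.outer(u, u)


@dataclass
class CellDecomposition:
    """Assignment of every particle to one cell of the randomly shifted grid.

    ``boost`` is the Lees-Edwards velocity adjustment (added to vx) that maps
    each particle into the frame of the cell it was imaged into; it is nonzero
    only for particles imaged through the sheared z-boundary by the grid
    shift. ``imaged`` flags those particles.
    """

    n_side: int
    shift: np.ndarray
    cell_ids: np.ndarray
    counts: np.ndarray
    boost: np.ndarray
    imaged: np.ndarray = field(repr=False)

    @property
    def n_cells(self) -> int:
        return self.n_side**3


def grid_shift_and_sort(
    positions: np.ndarray,
    L: float,
    a: float,
    rng: np.random.Generator | None = None,
    shift: np.ndarray | None = None,
    shear_offset: float = 0.0,
    gamma_dot: float = 0.0,
) -> CellDecomposition:
    """Draw a uniform grid shift in [-a/2, a/2]^3 and bin all particles.

    Positions must already be wrapped into [0, L)^3. Particles pushed past the
    z-boundary by the shift are imaged through the Lees-Edwards boundary
    (x-offset and vx-boost recorded) before binning; x and y wrap plainly.
    """
    n_side = int(round(L / a))
    if abs(n_side * a - L) > 1e-9 * L:
        raise ValueError("box edge L must be a multiple of the cell size a")
    if shift is None:
        if rng is None:
            raise ValueError("provide either rng or an explicit shift")
        shift = rng.uniform(-a / 2.0, a / 2.0, size=3)
    shift = np.asarray(shift, dtype=float)
    s = positions - shift
    kz = np.floor(s[:, 2] / L)
    imaged = kz != 0.0
    if imaged.any():
        s[:, 2] -= kz * L
        s[:, 0] -= kz * shear_offset
    boost = -kz * gamma_dot * L
    np.mod(s[:, 0], L, out=s[:, 0])
    np.mod(s[:, 1], L, out=s[:, 1])
    idx = np.clip((s / a).astype(int), 0, n_side - 1)
    cell_ids = (idx[:, 0] * n_side + idx[:, 1]) * n_side + idx[:, 2]
    counts = np.bincount(cell_ids, minlength=n_side**3)
    return CellDecomposition(
        n_side=n_side,
        shift=shift,
        cell_ids=cell_ids,
        counts=counts,
        boost=boost,
        imaged=imaged,
    )


def _cell_com_velocity(cells, v_eff, masses):
    """Mass-weighted centre-of-mass velocity of each cell (the mixed
    solvent+monomer average) and the total mass per cell."""
    ids = cells.cell_ids
    nc = cells.n_cells
    mtot = np.bincount(ids, weights=masses, minlength=nc)
    vcm = np.empty((nc, 3))
    for k in range(3):
        mom = np.bincount(ids, weights=masses * v_eff[:, k], minlength=nc)
        vcm[:, k] = np.divide(mom, mtot, out=np.zeros(nc), where=mtot > 0)
    return vcm, mtot


def collide(
    cells: CellDecomposition,
    velocities: np.ndarray,
    masses: np.ndarray,
    alpha: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stochastic rotation collision; returns the post-collision velocities.

    In every cell with at least two members the velocities relative to the
    mass-weighted centre-of-mass velocity are rotated by ``alpha`` degrees
    about one random axis per cell. Per-cell momentum and centre-of-mass-frame
    kinetic energy are conserved exactly. Lees-Edwards-imaged particles take
    part in the boosted frame of their cell.
    """
    if cells is None or len(cells.cell_ids) == 0:
        raise CombflowError("collide: empty cell decomposition")
    ids = cells.cell_ids
    nc = cells.n_cells
    masses = np.broadcast_to(np.asarray(masses, dtype=float), (len(ids),))
    v_eff = velocities.copy()
    v_eff[:, 0] += cells.boost
    vcm, _ = _cell_com_velocity(cells, v_eff, masses)
    vrel = v_eff - vcm[ids]
    axes = rng.normal(size=(nc, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    th = np.deg2rad(alpha)
    c, sn = np.cos(th), np.sin(th)
    u = axes[ids]
    udotv = np.einsum("ij,ij->i", u, vrel)
    vrot = c * vrel + sn * np.cross(u, vrel) + (1 - c) * udotv[:, None] * u
    active = cells.counts[ids] >= 2
    v_new = np.where(active[:, None], vcm[ids] + vrot, v_eff)
    v_new[:, 0] -= cells.boost
    return v_new


def cell_thermostat(
    cells: CellDecomposition,
    velocities: np.ndarray,
    masses: np.ndarray,
    kBT: float,
    rng: np.random.Generator,
    mode: str = "mbs",
) -> np.ndarray:
    """Cell-level thermostat acting on velocities relative to the cell COM.

    'mbs' (Maxwell-Boltzmann scaling) draws the target relative kinetic energy
    of each cell from the canonical Gamma distribution with 3(Nc-1) degrees of
    freedom and rescales the relative velocities to it, so equilibrium
    velocity distributions are exactly Maxwellian. 'rescale' pins each cell's
    instantaneous relative temperature to kBT. Either way the cell COM
    velocity is untouched, so momentum is preserved; cells with fewer than two
    members are skipped.
    """
    if mode == "none":
        return velocities
    ids = cells.cell_ids
    nc = cells.n_cells
    masses = np.broadcast_to(np.asarray(masses, dtype=float), (len(ids),))
    v_eff = velocities.copy()
    v_eff[:, 0] += cells.boost
    vcm, _ = _cell_com_velocity(cells, v_eff, masses)
    vrel = v_eff - vcm[ids]
    ek = 0.5 * np.bincount(
        ids, weights=masses * np.einsum("ij,ij->i", vrel, vrel), minlength=nc
    )
    dof = 3.0 * (cells.counts - 1.0)
    ok = (cells.counts >= 2) & (ek > 0.0)
    if mode == "mbs":
        target = np.zeros(nc)
        target[ok] = rng.gamma(shape=dof[ok] / 2.0, scale=kBT)
    elif mode == "rescale":
        target = 0.5 * dof * kBT
    else:
        raise ValueError(f"unknown thermostat mode {mode!r}")
    xi = np.ones(nc)
    xi[ok] = np.sqrt(target[ok] / ek[ok])
    v_new = vcm[ids] + xi[ids, None] * vrel
    apply = ok[ids]
    v_new = np.where(apply[:, None], v_new, v_eff)
    v_new[:, 0] -= cells.boost
    return v_new


def relative_kinetic_temperature(
    cells: CellDecomposition, velocities: np.ndarray, masses: np.ndarray
) -> float:
    """Kinetic temperature from velocities relative to each cell's COM
    (insensitive to the imposed flow on scales above one cell)."""
    ids = cells.cell_ids
    masses = np.broadcast_to(np.asarray(masses, dtype=float), (len(ids),))
    v_eff = velocities.copy()
    v_eff[:, 0] += cells.boost
    vcm, _ = _cell_com_velocity(cells, v_eff, masses)
    vrel = v_eff - vcm[ids]
    ek = 0.5 * float(np.sum(masses * np.einsum("ij,ij->i", vrel, vrel)))
    dof = 3.0 * float(np.sum(cells.counts[cells.counts >= 2] - 1))
    return 2.0 * ek / dof


def kinetic_theory_viscosity(params: FluidParams, parts: bool = False):
    """Closed-form SRD shear viscosity eta = rho (nu_kin + nu_coll).

    Standard molecular-chaos kinetic theory for the SRD collision rule with
    fluctuating cell occupancy at mean density M = mean_density:

        nu_kin  = (kBT h / 2m) [ 5M / ((M-1+e^-M)(2 - cos a - cos 2a)) - 1 ]
        nu_coll = (a^2 / 18h) (1 - cos a) (1 - (1 - e^-M)/M)

    At the liquid-like parameter point (alpha=130 deg, h=0.1, M=10,
    a = m = kBT = 1) this evaluates to 8.70 in units of sqrt(m kBT)/a^2.
    """
    al = np.deg2rad(params.alpha)
    M = params.mean_density
    m, kBT, h, a = params.solvent_mass, params.kBT, params.h, params.a
    with np.errstate(divide="ignore"):  # alpha = 0 has no kinetic relaxation
        nu_kin = (kBT * h / (2.0 * m)) * (
            5.0 * M / ((M - 1.0 + np.exp(-M)) * (2.0 - np.cos(al) - np.cos(2 * al)))
            - 1.0
        )
    nu_coll = (a**2 / (18.0 * h)) * (1.0 - np.cos(al)) * (1.0 - (1.0 - np.exp(-M)) / M)
    rho = m * M / a**3
    if parts:
        return rho * nu_kin, rho * nu_coll
    return float(rho * (nu_kin + nu_coll))


@dataclass
class VelocityProfile:
    z: np.ndarray
    vx: np.ndarray
    slope: float
    intercept: float


def measure_velocity_profile(frames, L: float, n_bins: int = 16) -> VelocityProfile:
    """Bin mean vx against z over steady-state frames and fit a line.

    ``frames`` is a sequence of SolventState or (positions, velocities)
    pairs. In the Lees-Edwards frame the steady profile is antisymmetric
    about the box centre, vx = gamma_dot * (z - L/2); the fitted slope
    estimates gamma_dot.
    """
    frames = list(frames)
    if len(frames) < 2:
        raise CombflowError("measure_velocity_profile: need at least 2 frames")
    sums = np.zeros(n_bins)
    cnts = np.zeros(n_bins)
    for fr in frames:
        pos, vel = (fr.positions, fr.velocities) if isinstance(fr, SolventState) else fr
        b = np.clip((pos[:, 2] / (L / n_bins)).astype(int), 0, n_bins - 1)
        sums += np.bincount(b, weights=vel[:, 0], minlength=n_bins)
        cnts += np.bincount(b, minlength=n_bins)
    vx = sums / np.maximum(cnts, 1)
    z = (np.arange(n_bins) + 0.5) * (L / n_bins)
    slope, intercept = np.polyfit(z - L / 2.0, vx, 1)
    return VelocityProfile(z=z, vx=vx, slope=float(slope), intercept=float(intercept))


@dataclass
class FluidRunResult:
    """Summary of a fluid-only run (Couette if gamma_dot > 0)."""

    params: FluidParams
    L: float
    n_particles: int
    n_steps: int
    kBT: float
    profile: VelocityProfile
    viscosity: float | None
    velocity_samples: np.ndarray | None
    state: SolventState


def run_fluid(
    params: FluidParams,
    n_side: int = 16,
    n_steps: int = 4000,
    seed: int = 0,
    warmup: int = 500,
    profile_bins: int = 16,
    sample_stride: int = 5,
    collect_velocities: int = 0,
) -> FluidRunResult:
    """Fluid-only MPCD run measuring temperature, profile and viscosity.

    With ``gamma_dot > 0`` the shear viscosity is measured from the momentum
    flux through the mid-plane z = L/2: the advective flux counts x-momentum
    carried by particles crossing the plane while streaming, the collisional
    flux counts the x-momentum handed across the plane inside cells that span
    it during collision + thermostat. eta = -<flux>/gamma_dot. Up to
    ``collect_velocities`` raw velocity samples are returned for distribution
    tests.
    """
    rng = np.random.default_rng(seed)
    L = n_side * params.a
    state = initialize_solvent(L, params, rng, linear_profile=params.gamma_dot != 0)
    m = params.solvent_mass
    z0 = L / 2.0
    area = L * L
    flux_sum = 0.0
    n_flux = 0
    temp_sum = 0.0
    n_temp = 0
    prof_sums = np.zeros(profile_bins)
    prof_cnts = np.zeros(profile_bins)
    vel_samples: list[np.ndarray] = []
    for step in range(n_steps):
        measuring = step >= warmup
        if measuring and params.gamma_dot != 0:
            zpre = state.positions[:, 2]
            zpost = zpre + state.velocities[:, 2] * params.h
            crossed = (zpre - z0) * (zpost - z0) < 0.0
            if crossed.any():
                flux_sum += m * float(
                    np.sum(
                        state.velocities[crossed, 0]
                        * np.sign(state.velocities[crossed, 2])
                    )
                )
        stream(state, params.h, params.gamma_dot)
        cells = grid_shift_and_sort(
            state.positions,
            L,
            params.a,
            rng=rng,
            shear_offset=state.shear_offset,
            gamma_dot=params.gamma_dot,
        )
        v_old = state.velocities
        v = collide(cells, v_old, m, params.alpha, rng)
        v = cell_thermostat(cells, v, m, params.kBT, rng, params.thermostat)
        state.velocities = v
        if measuring:
            if params.gamma_dot != 0:
                excl = np.bincount(
                    cells.cell_ids,
                    weights=cells.imaged.astype(float),
                    minlength=cells.n_cells,
                )
                keep = (state.positions[:, 2] > z0) & (excl[cells.cell_ids] == 0)
                flux_sum += m * float(np.sum(v[keep, 0] - v_old[keep, 0]))
                n_flux += 1
            if step % sample_stride == 0:
                temp_sum += relative_kinetic_temperature(cells, v, m)
                n_temp += 1
                b = np.clip(
                    (state.positions[:, 2] / (L / profile_bins)).astype(int),
                    0,
                    profile_bins - 1,
                )
                prof_sums += np.bincount(b, weights=v[:, 0], minlength=profile_bins)
                prof_cnts += np.bincount(b, minlength=profile_bins)
                want = collect_velocities - sum(len(s) for s in vel_samples)
                if want > 0:
                    vel_samples.append(v[: min(want, len(v))].copy())
    vx = prof_sums / np.maximum(prof_cnts, 1)
    z = (np.arange(profile_bins) + 0.5) * (L / profile_bins)
    slope, intercept = np.polyfit(z - L / 2.0, vx, 1)
    profile = VelocityProfile(z, vx, float(slope), float(intercept))
    eta = None
    if params.gamma_dot != 0 and n_flux > 0:
        mean_flux = flux_sum / (n_flux * area * params.h)
        eta = -mean_flux / params.gamma_dot
    return FluidRunResult(
        params=params,
        L=L,
        n_particles=state.n,
        n_steps=n_steps,
        kBT=temp_sum / max(n_temp, 1),
        profile=profile,
        viscosity=eta,
        velocity_samples=np.concatenate(vel_samples) if vel_samples else None,
        state=state,
    )
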