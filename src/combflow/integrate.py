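"""Hybrid integrator: velocity-Verlet MD for the comb, MPCD for the solvent.

The polymer obeys Newton's equations under the WCA + FENE forces, integrated
with velocity-Verlet at a time step ``hp`` (default 0.005 tau). Every
collision time ``h`` (default 0.1 tau, i.e. 20 MD substeps) the solvent
streams ballistically and polymer beads join the solvent particles in the
stochastic rotation collision with their mass M entering the cell
centre-of-mass average — collisions are the only solvent-polymer coupling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .box import ShearBox
from .errors import ConfigError, IntegrationError
from .fluid import (
    FluidParams,
    SolventState,
    cell_thermostat,
    collide,
    grid_shift_and_sort,
    initialize_solvent,
)
from .model import (
    CombTopology,
    ModelParams,
    compute_polymer_forces,
    init_polymer_configuration,
)
from . import observables as obs
from .trajectory import TrajectoryFrame

log = logging.getLogger("combflow")


@dataclass
class SystemState:
    """Full phase space of solvent plus polymer, with integrator bookkeeping."""

    solvent: SolventState
    polymer_positions: np.ndarray
    polymer_velocities: np.ndarray
    polymer_forces: np.ndarray
    topology: CombTopology
    model: ModelParams
    fluid: FluidParams
    rng: np.random.Generator
    time: float = 0.0
    step: int = 0  # collision steps taken

    @property
    def n_sub(self) -> int:
        from .config import substeps_per_collision

        return substeps_per_collision(self.fluid.h, hp=self.hp)

    hp: float = 0.005

    @property
    def box(self) -> ShearBox:
        return self.solvent.box

    def total_momentum(self) -> np.ndarray:
        p = self.fluid.solvent_mass * self.solvent.velocities.sum(axis=0)
        p = p + self.model.monomer_mass * self.polymer_velocities.sum(axis=0)
        return p

    def polymer_kinetic_temperature(self) -> float:
        v = self.polymer_velocities
        n = len(v)
        return float(self.model.monomer_mass * np.sum(v * v) / (3.0 * n))


def relax_polymer(
    positions: np.ndarray,
    topology: CombTopology,
    model: ModelParams,
    box: ShearBox,
    rng: np.random.Generator,
    kBT: float = 1.0,
    n_steps: int = 300,
    hp: float = 0.005,
    force_cap: float = 100.0,
) -> np.ndarray:
    """Short force-capped warm-up that anneals grown configurations.

    Runs damped, force-capped MD with velocity re-thermalization so that
    residual WCA overlaps from the self-avoiding growth relax before the
    solvent is coupled. Returns the relaxed positions (in place).
    """
    M = model.monomer_mass
    vel = rng.normal(scale=np.sqrt(kBT / M), size=positions.shape)
    vel -= vel.mean(axis=0)
    for i in range(n_steps):
        f = compute_polymer_forces(positions, topology, model, box)
        fn = np.linalg.norm(f, axis=1, keepdims=True)
        f = np.where(fn > force_cap, f * (force_cap / fn), f)
        vel += f * (hp / M)
        vel *= 0.95  # mild damping
        positions += vel * hp
        box.wrap(positions, vel, 0.0)
        if i % 50 == 49:
            vel = rng.normal(scale=np.sqrt(kBT / M), size=positions.shape)
            vel -= vel.mean(axis=0)
    return positions


def velocity_verlet_substep(state: SystemState, hp: float | None = None) -> SystemState:
    """One velocity-Verlet substep for the polymer (half-kick, drift,
    half-kick), with Lees-Edwards wrapping of positions after the drift.

    The Lees-Edwards offset advances with the substep so minimum images stay
    consistent; the solvent does not move here.
    """
    hp = state.hp if hp is None else hp
    M = state.model.monomer_mass
    g = state.fluid.gamma_dot
    state.polymer_velocities += state.polymer_forces * (0.5 * hp / M)
    state.polymer_positions += state.polymer_velocities * hp
    state.solvent.advance_offset(hp, g)
    state.time += hp
    state.box.wrap(state.polymer_positions, state.polymer_velocities, g)
    state.polymer_forces = compute_polymer_forces(
        state.polymer_positions, state.topology, state.model, state.box
    )
    state.polymer_velocities += state.polymer_forces * (0.5 * hp / M)
    return state


def hybrid_step(state: SystemState) -> SystemState:
    """Advance one collision interval h: MD substeps, solvent streaming,
    grid shift, joint collision with mass-weighted cell averages, thermostat.
    """
    f = state.fluid
    n_sub = state.n_sub
    for _ in range(n_sub):
        velocity_verlet_substep(state)
    sol = state.solvent
    # solvent streams ballistically once per collision interval; the offset
    # was already advanced through the MD substeps
    sol.positions += sol.velocities * f.h
    sol.box.wrap(sol.positions, sol.velocities, f.gamma_dot)

    n_s, n_m = sol.n, len(state.polymer_positions)
    all_pos = np.concatenate([sol.positions, state.polymer_positions])
    all_vel = np.concatenate([sol.velocities, state.polymer_velocities])
    masses = np.concatenate(
        [np.full(n_s, f.solvent_mass), np.full(n_m, state.model.monomer_mass)]
    )
    cells = grid_shift_and_sort(
        all_pos,
        sol.L,
        f.a,
        rng=state.rng,
        shear_offset=sol.shear_offset,
        gamma_dot=f.gamma_dot,
    )
    all_vel = collide(cells, all_vel, masses, f.alpha, state.rng)
    all_vel = cell_thermostat(cells, all_vel, masses, f.kBT, state.rng, f.thermostat)
    sol.velocities = all_vel[:n_s]
    state.polymer_velocities = all_vel[n_s:]
    if not (
        np.all(np.isfinite(state.polymer_positions))
        and np.all(np.isfinite(all_vel))
    ):
        raise IntegrationError(
            f"non-finite coordinates or velocities at collision step {state.step}"
        )
    state.step += 1
    if state.step % 1000 == 0:
        R, _ = obs.end_to_end_backbone(
            obs.unwrap_molecule(state.polymer_positions, state.topology, state.box),
            state.topology,
        )
        log.info(
            "step=%d t=%.1f kBT_poly=%.3f |p|=%.3e Rete_back=%.2f",
            state.step,
            state.time,
            state.polymer_kinetic_temperature(),
            float(np.linalg.norm(state.total_momentum())),
            float(np.linalg.norm(R)),
        )
    return state


def build_system(config, rng: np.random.Generator | None = None) -> SystemState:
    """Assemble solvent + polymer from a RunConfig (see combflow.config)."""
    from .config import RunConfig  # local import to avoid a cycle

    if not isinstance(config, RunConfig):
        raise ConfigError("build_system expects a RunConfig")
    ss = np.random.SeedSequence(config.seed)
    s_init, s_poly, s_dyn = ss.spawn(3)
    if rng is None:
        rng = np.random.default_rng(s_dyn)
    fluid = config.fluid_params()
    model = config.model_params()
    topo = config.topology()
    sol = initialize_solvent(config.L, fluid, np.random.default_rng(s_init))
    box = ShearBox(config.L)
    pos, vel = init_polymer_configuration(
        topo, box, seed=int(s_poly.generate_state(1)[0] % 2**31), params=model,
        kBT=fluid.kBT,
    )
    relax_polymer(pos, topo, model, box, np.random.default_rng(s_poly), kBT=fluid.kBT)
    forces = compute_polymer_forces(pos, topo, model, box)
    return SystemState(
        solvent=sol,
        polymer_positions=pos,
        polymer_velocities=vel,
        polymer_forces=forces,
        topology=topo,
        model=model,
        fluid=fluid,
        rng=rng,
        hp=config.hp,
    )


@dataclass
class SimulationResult:
    """Frames, per-frame observables and provenance of one run."""

    frames: list = field(repr=False)
    observables: pd.DataFrame = field(repr=False)
    manifest: dict
    topology: CombTopology
    state: SystemState = field(repr=False)


def _frame_observables(state: SystemState) -> dict:
    unwrapped = obs.unwrap_molecule(
        state.polymer_positions, state.topology, state.box
    )
    R, mag = obs.end_to_end_backbone(unwrapped, state.topology)
    row = {
        "t": state.time,
        "Rete_back": mag,
        "Gxx": np.nan,
        "Gyy": np.nan,
        "Gzz": np.nan,
        "Gxz": np.nan,
        "RG2": np.nan,
        "cos_theta": np.nan,
        "theta": np.nan,
        "Rete_arm_mean": np.nan,
        "sigma_xz": np.nan,
    }
    g = obs.gyration_tensor(unwrapped)
    row.update(
        Gxx=g.G[0, 0], Gyy=g.G[1, 1], Gzz=g.G[2, 2], Gxz=g.G[0, 2], RG2=g.RG2
    )
    if abs(R[0]) + abs(R[2]) > 0:
        th = obs.backbone_angle(R)
        row.update(theta=th, cos_theta=np.cos(th))
    if state.topology.Na >= 1 and state.topology.La >= 2:
        row.update(
            Rete_arm_mean=obs.mean_arm_end_to_end(unwrapped, state.topology)
        )
    from .estimators import shear_virial_stress

    row.update(
        sigma_xz=shear_virial_stress(
            state.polymer_positions,
            state.topology,
            state.model,
            state.box,
            volume=state.solvent.L**3,
        )
    )
    return row


def run_simulation(config, include_solvent_frames: bool = False) -> SimulationResult:
    """Run warm-up plus production and collect frames and observables.

    Durations (``warmup``, ``production``) are in tau and are rounded to whole
    collision steps; frames are emitted every ``frame_stride`` and observable
    rows every ``obs_stride`` collision steps of the production phase. The
    same seed reproduces the identical observable series bit for bit.
    """
    state = build_system(config)
    n_warm = int(round(config.warmup / config.h))
    n_prod = int(round(config.production / config.h))
    for _ in range(n_warm):
        hybrid_step(state)
    frames: list[TrajectoryFrame] = []
    rows: list[dict] = []
    species = state.topology.species
    for i in range(n_prod):
        hybrid_step(state)
        if i % config.obs_stride == 0:
            rows.append(_frame_observables(state))
        if i % config.frame_stride == 0:
            if include_solvent_frames:
                frames.append(
                    TrajectoryFrame(
                        time=state.time,
                        L=state.solvent.L,
                        shear_offset=state.solvent.shear_offset,
                        species=np.concatenate(
                            [species, np.full(state.solvent.n, "S")]
                        ),
                        positions=np.concatenate(
                            [state.polymer_positions, state.solvent.positions]
                        ),
                        velocities=np.concatenate(
                            [state.polymer_velocities, state.solvent.velocities]
                        ),
                    )
                )
            else:
                frames.append(
                    TrajectoryFrame(
                        time=state.time,
                        L=state.solvent.L,
                        shear_offset=state.solvent.shear_offset,
                        species=species.copy(),
                        positions=state.polymer_positions.copy(),
                        velocities=state.polymer_velocities.copy(),
                    )
                )
    manifest = {"config": config.to_dict(), "seed": config.seed, "version": __version__()}
    return SimulationResult(
        frames=frames,
        observables=pd.DataFrame(rows),
        manifest=manifest,
        topology=state.topology,
        state=state,
    )


def __version__() -> str:
    from importlib.metadata import version

    try:
        return version("combflow")
    except Exception:
        return "unknown"
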