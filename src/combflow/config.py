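"""Run configuration: defaults, validation, YAML round-trip.

The defaults are the reference parameter set of the study conditions:
collision time h = 0.1 tau, MD step hp = 0.005 tau (20 substeps), cell edge
a = sigma, rotation angle 130 degrees, 10 solvent particles per cell, monomer
mass M = 10 m, FENE K = 30 eps/sigma^2 and l0 = 1.5 sigma, box L = 100 sigma,
comb Lb = La = 20 with one arm per backbone bead. An empty config file is a
valid config equal to these defaults; unknown keys are rejected by name.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import numpy as np
import yaml

from .errors import ConfigError
from .fluid import FluidParams
from .model import CombTopology, ModelParams, build_comb


def substeps_per_collision(h: float, hp: float) -> int:
    n = h / hp
    if abs(n - round(n)) > 1e-9 or round(n) < 1:
        raise ConfigError(f"h/hp must be a positive integer (h={h}, hp={hp})")
    return int(round(n))


@dataclass
class RunConfig:
    """Everything needed to reproduce one run: model, fluid, flow, durations."""

    # comb topology
    Lb: int = 20
    La: int = 20
    Na: int | None = None  # None -> one arm per backbone bead (Na = Lb)
    # bead-spring model
    epsilon: float = 1.0
    sigma: float = 1.0
    l0: float = 1.5
    K: float = 30.0
    monomer_mass: float = 10.0
    shift_wca: bool = True
    # fluid
    h: float = 0.1
    hp: float = 0.005
    a: float = 1.0
    alpha: float = 130.0
    mean_density: float = 10.0
    solvent_mass: float = 1.0
    kBT: float = 1.0
    thermostat: str = "mbs"
    # flow and box
    gamma_dot: float = 0.0
    L: float = 100.0
    # run control
    seed: int = 0
    warmup: float = 50.0  # tau
    production: float = 200.0  # tau
    frame_stride: int = 10  # collision steps between trajectory frames
    obs_stride: int = 1  # collision steps between observable rows
    trajectory_path: str | None = None
    observables_path: str | None = None

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.Lb < 1 or self.La < 0 or (self.Na is not None and self.Na < 0):
            raise ConfigError("Lb must be >= 1 and La, Na nonnegative")
        if self.Na is not None and self.Na > self.Lb:
            raise ConfigError(f"Na={self.Na} exceeds backbone length Lb={self.Lb}")
        for key in ("epsilon", "sigma", "l0", "K", "monomer_mass", "h", "hp", "a",
                    "solvent_mass", "kBT", "L"):
            if getattr(self, key) <= 0:
                raise ConfigError(f"{key} must be positive")
        if not 0.0 <= self.alpha <= 180.0:
            raise ConfigError(f"alpha={self.alpha} outside [0, 180] degrees")
        if self.mean_density < 1:
            raise ConfigError("mean_density must be >= 1")
        substeps_per_collision(self.h, self.hp)
        if abs(self.L / self.a - round(self.L / self.a)) > 1e-9:
            raise ConfigError(f"L={self.L} must be a multiple of the cell size a={self.a}")
        if self.thermostat not in ("mbs", "rescale", "none"):
            raise ConfigError(f"unknown thermostat {self.thermostat!r}")
        if self.warmup < 0 or self.production <= 0:
            raise ConfigError("warmup must be >= 0 and production > 0")
        if self.frame_stride < 1 or self.obs_stride < 1:
            raise ConfigError("strides must be >= 1")

    # -- derived objects ----------------------------------------------------
    def effective_Na(self) -> int:
        return self.Lb if self.Na is None else self.Na

    def topology(self) -> CombTopology:
        return build_comb(self.Lb, self.La, self.effective_Na())

    def model_params(self) -> ModelParams:
        return ModelParams(
            epsilon=self.epsilon,
            sigma=self.sigma,
            l0=self.l0,
            K=self.K,
            monomer_mass=self.monomer_mass,
            shift_wca=self.shift_wca,
        )

    def fluid_params(self) -> FluidParams:
        return FluidParams(
            h=self.h,
            a=self.a,
            alpha=self.alpha,
            mean_density=self.mean_density,
            solvent_mass=self.solvent_mass,
            kBT=self.kBT,
            gamma_dot=self.gamma_dot,
            thermostat=self.thermostat,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    """Read a YAML config; unknown keys and constraint violations raise
    ConfigError naming the offending key. An empty file yields the defaults."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except FileNotFoundError:
        raise ConfigError(f"config file not found: {path}")
    except yaml.YAMLError as e:
        raise ConfigError(f"malformed YAML in {path}: {e}")
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    known = {f.name: f for f in fields(RunConfig)}
    unknown = set(raw) - set(known)
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(sorted(unknown))}")
    coerced = {}
    for key, val in raw.items():
        want = known[key].type
        if val is None:
            coerced[key] = None
            continue
        try:
            if want.startswith("int"):
                if float(val) != int(val):
                    raise ValueError
                coerced[key] = int(val)
            elif want.startswith("float"):
                coerced[key] = float(val)
            elif want.startswith("bool"):
                if not isinstance(val, bool):
                    raise ValueError
                coerced[key] = val
            else:
                coerced[key] = val
        except (TypeError, ValueError):
            raise ConfigError(f"config key {key!r}: cannot interpret {val!r}")
    try:
        return RunConfig(**coerced)
    except TypeError as e:
        raise ConfigError(str(e))


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
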