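"""Synthetic inputs with known ground truth.

Each generator returns its data together with a ``truth`` dict holding the
parameters that produced it, so estimator tests assert recovery against the
stored truth rather than re-derived values. Noise is additive Gaussian
throughout, and the seed fully determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CombflowError
from .fluid import FluidParams, SolventState, initialize_solvent


@dataclass
class Fixture:
    """Data plus the ground truth that generated it."""

    data: object
    truth: dict


def rigid_rotor_series(
    omega: float,
    duration: float,
    dt: float,
    noise: float = 0.0,
    seed: int = 0,
    phi0: float | None = None,
) -> Fixture:
    """Noisy rigid-rotation orientation series cos(omega t + phi0) + eps,
    clipped to [-1, 1]; the target of the periodic tumbling fit."""
    if duration < 3.0 * (2.0 * np.pi / omega):
        raise CombflowError("rigid_rotor_series: duration must cover >= 3 periods")
    rng = np.random.default_rng(seed)
    if phi0 is None:
        phi0 = float(rng.uniform(0, 2 * np.pi))
    t = np.arange(0.0, duration, dt)
    y = np.cos(omega * t + phi0)
    if noise > 0:
        y = y + rng.normal(scale=noise, size=t.shape)
    y = np.clip(y, -1.0, 1.0)
    return Fixture(
        data=(t, y),
        truth={"omega": omega, "phi0": phi0, "dt": dt, "noise": noise, "seed": seed},
    )


def exp_decay_correlation(
    tau: float, duration: float, dt: float, noise: float = 0.0, seed: int = 0
) -> Fixture:
    """Exponentially decaying correlation exp(-t/tau) + eps with C(0) = 1
    enforced; the target of the relaxation-time fit."""
    if not np.isfinite(tau):
        raise CombflowError("exp_decay_correlation: tau must be finite (non-decaying)")
    if duration < 5.0 * tau:
        raise CombflowError("exp_decay_correlation: duration must cover >= 5 tau")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, dt)
    C = np.exp(-t / tau)
    if noise > 0:
        C = C + rng.normal(scale=noise, size=t.shape)
    C[0] = 1.0
    return Fixture(
        data=(t, C), truth={"tau": tau, "dt": dt, "noise": noise, "seed": seed}
    )


def analytic_point_cloud(shape: str, n: int = 21, length: float = 20.0) -> Fixture:
    """Static point clouds with closed-form gyration tensors.

    'segment': n beads equally spaced on a segment of length ``length`` along
    x, Gxx = length^2 (n+1) / (12 (n-1)); 'rectangle': an n x n grid in the
    xy plane; 'coincident': all beads at one point (zero tensor).
    """
    G = np.zeros((3, 3))
    if shape == "coincident":
        pos = np.zeros((n, 3))
    elif shape == "segment":
        pos = np.zeros((n, 3))
        pos[:, 0] = np.linspace(0.0, length, n)
        G[0, 0] = length**2 * (n + 1) / (12.0 * (n - 1))
    elif shape == "rectangle":
        xs = np.linspace(0.0, length, n)
        X, Y = np.meshgrid(xs, xs)
        pos = np.column_stack([X.ravel(), Y.ravel(), np.zeros(n * n)])
        G[0, 0] = G[1, 1] = length**2 * (n + 1) / (12.0 * (n - 1))
    else:
        raise CombflowError(f"analytic_point_cloud: unknown shape {shape!r}")
    return Fixture(data=pos, truth={"G": G, "shape": shape})


def gaussian_chain_frames(
    N: int, bond_b: float = 1.0, n_frames: int = 1000, seed: int = 0
) -> Fixture:
    """Ideal random-walk chains: the equilibrium null model for end-to-end
    PDFs, with <Rete^2> = (N-1) b^2 exactly."""
    if N < 2:
        raise CombflowError("gaussian_chain_frames: need N >= 2")
    rng = np.random.default_rng(seed)
    steps = rng.normal(scale=bond_b / np.sqrt(3.0), size=(n_frames, N - 1, 3))
    pos = np.concatenate(
        [np.zeros((n_frames, 1, 3)), np.cumsum(steps, axis=1)], axis=1
    )
    return Fixture(
        data=pos,
        truth={"N": N, "b": bond_b, "mean_sq_ete": (N - 1) * bond_b**2, "seed": seed},
    )


def thermal_fluid_ic(
    L: float, density: float = 10.0, kBT: float = 1.0, seed: int = 0, a: float = 1.0
) -> Fixture:
    """Thermalized solvent initial condition: uniform positions, Maxwellian
    velocities at kBT, zero net momentum, ~``density`` particles per cell."""
    if abs(L / a - round(L / a)) > 1e-9:
        raise CombflowError("thermal_fluid_ic: L must be a multiple of a")
    params = FluidParams(a=a, mean_density=density, kBT=kBT)
    state = initialize_solvent(L, params, np.random.default_rng(seed))
    return Fixture(
        data=state,
        truth={"L": L, "density": density, "kBT": kBT, "seed": seed},
    )
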