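"""Trajectory frames, extended-XYZ I/O and tidy observable tables.

The trajectory dialect is plain extended XYZ: a bead-count line, a comment
line of ``key=value`` pairs (time, box edge, Lees-Edwards shear offset), then
one row per bead with a species tag (B backbone / A arm / S solvent), the
position and the velocity, written with 9 significant digits so frames
round-trip bit-stably at output precision.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CombflowError


@dataclass
class TrajectoryFrame:
    """One time-stamped snapshot (polymer, optionally with solvent)."""

    time: float
    L: float
    shear_offset: float
    species: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray

    @property
    def n(self) -> int:
        return len(self.positions)


def write_trajectory_frame(frame: TrajectoryFrame, stream: io.TextIOBase) -> None:
    stream.write(f"{frame.n}\n")
    stream.write(
        f"time={frame.time:.9g} box={frame.L:.9g} "
        f"shear_offset={frame.shear_offset:.9g}\n"
    )
    for sp, r, v in zip(frame.species, frame.positions, frame.velocities):
        stream.write(
            f"{sp} {r[0]:.9g} {r[1]:.9g} {r[2]:.9g} "
            f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n"
        )


def write_trajectory(frames, path) -> None:
    with open(path, "w") as fh:
        for frame in frames:
            write_trajectory_frame(frame, fh)


def read_trajectory(path) -> list[TrajectoryFrame]:
    """Parse an extended-XYZ trajectory; errors carry the offending line."""
    frames: list[TrajectoryFrame] = []
    with open(path) as fh:
        lines = fh.readlines()
    ln = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            n = int(lines[ln].strip())
        except ValueError:
            raise CombflowError(f"{path}:{ln + 1}: expected bead count")
        if ln + 1 + n >= len(lines) + 1 and n > 0:
            raise CombflowError(f"{path}:{ln + 1}: truncated frame ({n} beads)")
        meta = {}
        for tok in lines[ln + 1].split():
            if "=" not in tok:
                raise CombflowError(f"{path}:{ln + 2}: bad key=value token {tok!r}")
            k, v = tok.split("=", 1)
            meta[k] = float(v)
        species = np.empty(n, dtype=object)
        pos = np.empty((n, 3))
        vel = np.empty((n, 3))
        for i in range(n):
            parts = lines[ln + 2 + i].split()
            if len(parts) != 7:
                raise CombflowError(
                    f"{path}:{ln + 3 + i}: expected 7 columns, got {len(parts)}"
                )
            species[i] = parts[0]
            pos[i] = [float(x) for x in parts[1:4]]
            vel[i] = [float(x) for x in parts[4:7]]
        frames.append(
            TrajectoryFrame(
                time=meta.get("time", 0.0),
                L=meta.get("box", 0.0),
                shear_offset=meta.get("shear_offset", 0.0),
                species=species.astype(str),
                positions=pos,
                velocities=vel,
            )
        )
        ln += 2 + n
    return frames


def summarize_run(
    result,
    tau_eq: float | None = None,
    stretched_quantile: float = 0.01,
) -> dict:
    """Steady-state summary of one run at one shear rate.

    Returns mean gyration components, RG2, the alignment parameter, the
    orientation resistance (when tau_eq is known), the tumbling frequency from
    the cos(theta) series and the fully-stretched backbone length.
    """
    from . import observables as obs
    from .estimators import fit_tumbling, weissenberg

    df = result.observables
    gamma_dot = result.manifest["config"]["gamma_dot"]
    g = obs.GyrationSummary(
        G=np.array(
            [
                [df.Gxx.mean(), 0.0, df.Gxz.mean()],
                [0.0, df.Gyy.mean(), 0.0],
                [df.Gxz.mean(), 0.0, df.Gzz.mean()],
            ]
        ),
        RG2=float(df.RG2.mean()),
    )
    Wi = weissenberg(gamma_dot, tau_eq) if tau_eq else None
    obs.alignment(g, Wi if (Wi and Wi > 0) else None)
    row = {
        "gamma_dot": gamma_dot,
        "Wi": Wi if Wi is not None else np.nan,
        "Gxx": float(df.Gxx.mean()),
        "Gyy": float(df.Gyy.mean()),
        "Gzz": float(df.Gzz.mean()),
        "Gxz": float(df.Gxz.mean()),
        "RG2": g.RG2,
        "tan2chi": g.tan2chi,
        "mG": g.mG if g.mG is not None else np.nan,
        "omega_TB": np.nan,
        "stretched_length": np.nan,
        "theta_stretched": np.nan,
    }
    series = df.dropna(subset=["cos_theta"])
    if len(series) >= 100:
        fit = fit_tumbling(series.t.to_numpy(), series.cos_theta.to_numpy())
        if fit.converged:
            row["omega_TB"] = fit.omega
    try:
        row["stretched_length"] = obs.fully_stretched_length(
            df.Rete_back.to_numpy(), q=stretched_quantile
        )
        top = df.nlargest(max(1, int(stretched_quantile * len(df))), "Rete_back")
        row["theta_stretched"] = float(top.theta.mean())
    except CombflowError:
        pass
    return row


def sweep_table(results, tau_eq: float | None = None) -> pd.DataFrame:
    """One row per shear rate: the quantities of the structural analysis
    (Wi, <G_ab>, RG2, tan2chi, mG, tumbling frequency, stretched length)."""
    return pd.DataFrame([summarize_run(r, tau_eq=tau_eq) for r in results])
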