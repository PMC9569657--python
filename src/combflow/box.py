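"""Periodic geometry with Lees-Edwards shear images.

The simulation box is a cube of edge ``L`` that is periodic in all three
directions. Under shear the z-images slide along x: a particle leaving through
the top face (z >= L) re-enters at the bottom displaced by the accumulated
boundary offset and with its x-velocity reduced by the boundary velocity jump
``gamma_dot * L`` (and conversely at the bottom face). The offset at time t is
``(gamma_dot * L * t) mod L``, so a linear Couette profile v = gamma_dot * z
can be sustained without walls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ShearBox:
    """Cubic periodic box with a Lees-Edwards x-offset between z-images.

    Parameters
    ----------
    L : float
        Box edge length (sigma).
    shear_offset : float
        Current x-displacement of the z+L image row, in [0, L).
    """

    L: float
    shear_offset: float = 0.0

    def minimum_image(self, d: np.ndarray) -> np.ndarray:
        """Return minimum-image displacement vectors (shear-aware).

        ``d`` has shape (..., 3). The z component is imaged first; each z-image
        crossing drags x by the current shear offset, then x and y are imaged
        plainly.
        """
        d = np.array(d, dtype=float, copy=True)
        L = self.L
        kz = np.round(d[..., 2] / L)
        d[..., 2] -= kz * L
        d[..., 0] -= kz * self.shear_offset
        d[..., 0] -= L * np.round(d[..., 0] / L)
        d[..., 1] -= L * np.round(d[..., 1] / L)
        return d

    def wrap(
        self, positions: np.ndarray, velocities: np.ndarray, gamma_dot: float
    ) -> None:
        """Wrap positions into [0, L)^3 in place, applying Lees-Edwards rules.

        A z-crossing by k boxes shifts x by -k*offset and vx by
        -k*gamma_dot*L; x and y are then wrapped periodically.
        """
        L = self.L
        kz = np.floor(positions[:, 2] / L)
        if np.any(kz != 0.0):
            positions[:, 2] -= kz * L
            positions[:, 0] -= kz * self.shear_offset
            velocities[:, 0] -= kz * gamma_dot * L
        np.mod(positions[:, 0], L, out=positions[:, 0])
        np.mod(positions[:, 1], L, out=positions[:, 1])

    def copy(self) -> "ShearBox":
        return ShearBox(self.L, self.shear_offset)


def offset_at(L: float, gamma_dot: float, t: float) -> float:
    """Accumulated Lees-Edwards offset gamma_dot*L*t, wrapped into [0, L)."""
    return float(np.mod(gamma_dot * L * t, L))
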