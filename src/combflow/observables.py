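"""Per-frame structural measurements of the comb polymer.

All shape measurements assume molecule-contiguous ("unwrapped") coordinates;
``unwrap_molecule`` rebuilds them from wrapped ones by walking the bond graph
with minimum-image displacements. The conventions follow the usual shear-flow
geometry: x is the flow direction, z the velocity-gradient direction, so
orientation lives in the xz (flow-gradient) plane.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .box import ShearBox
from .errors import CombflowError
from .model import CombTopology


def unwrap_molecule(
    positions: np.ndarray, topology: CombTopology, box: ShearBox | None
) -> np.ndarray:
    """Make the molecule contiguous across periodic images.

    Breadth-first traversal from bead 0: each bead is placed at its parent's
    position plus the minimum-image bond vector (shear-aware), so the result
    is independent of how the molecule was wrapped.
    """
    if box is None:
        return np.array(positions, dtype=float, copy=True)
    n = len(positions)
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in topology.bonds:
        adj[i].append(j)
        adj[j].append(i)
    out = np.array(positions, dtype=float, copy=True)
    seen = np.zeros(n, dtype=bool)
    seen[0] = True
    queue = deque([0])
    while queue:
        i = queue.popleft()
        for j in adj[i]:
            if not seen[j]:
                d = box.minimum_image(positions[j] - positions[i])
                out[j] = out[i] + d
                seen[j] = True
                queue.append(j)
    return out


def end_to_end(positions: np.ndarray, i: int, j: int):
    """End-to-end vector from bead i to bead j and its magnitude."""
    vec = np.asarray(positions[j], dtype=float) - np.asarray(positions[i], dtype=float)
    return vec, float(np.linalg.norm(vec))


def end_to_end_backbone(positions: np.ndarray, topology: CombTopology):
    """End-to-end vector of the backbone (bead 0 to bead Lb-1)."""
    return end_to_end(positions, 0, topology.Lb - 1)


def backbone_angle(R: np.ndarray) -> float:
    """Angle of the end-to-end vector against the flow direction in the
    flow-gradient plane: theta = arccos(Rx / sqrt(Rx^2 + Rz^2)) in [0, pi].
    """
    rx, rz = float(R[0]), float(R[2])
    h = np.hypot(rx, rz)
    if h == 0.0:
        raise CombflowError("backbone_angle: zero xz-projection, angle undefined")
    return float(np.arccos(np.clip(rx / h, -1.0, 1.0)))


def cos_backbone_angle(R: np.ndarray) -> float:
    """cos(theta_back) of the xz-projection, continuous in [-1, 1]."""
    return float(np.cos(backbone_angle(R)))


def sign_of_rx(R: np.ndarray) -> float:
    """Literal orientation indicator <R, x_hat>/|<R, x_hat>| (evaluates to
    +/-1); kept as a helper, the continuous cosine is the working quantity."""
    rx = float(R[0])
    if rx == 0.0:
        raise CombflowError("sign_of_rx: Rx = 0")
    return float(np.sign(rx))


def mean_arm_end_to_end(positions: np.ndarray, topology: CombTopology) -> float:
    """Arithmetic mean over arms of the root-to-tip end-to-end distance."""
    if topology.Na < 1 or topology.La < 2:
        raise CombflowError("mean_arm_end_to_end: need Na >= 1 and La >= 2")
    mags = []
    for k in range(topology.Na):
        arm = topology.arm(k)
        _, mag = end_to_end(positions, int(arm[0]), int(arm[-1]))
        mags.append(mag)
    return float(np.mean(mags))


@dataclass
class GyrationSummary:
    """Gyration tensor G (sigma^2), its trace RG2, and — when alignment is
    evaluated — the orientation angle chi_G, the alignment parameter
    tan(2 chi_G) and the orientation resistance mG = Wi * tan(2 chi_G)."""

    G: np.ndarray
    RG2: float
    chi_G: float | None = None
    tan2chi: float | None = None
    mG: float | None = None


def gyration_tensor(positions: np.ndarray) -> GyrationSummary:
    """G_ab = (1/N) sum_i r_ia r_ib about the bead centroid (all beads share
    one mass, so the centroid is the centre of mass); symmetric PSD."""
    pos = np.asarray(positions, dtype=float)
    rel = pos - pos.mean(axis=0)
    G = rel.T @ rel / len(pos)
    return GyrationSummary(G=G, RG2=float(np.trace(G)))


def alignment(g: GyrationSummary, Wi: float | None = None) -> GyrationSummary:
    """Fill chi_G, tan(2 chi_G) and (given Wi > 0) the orientation resistance.

    chi_G = 0.5 atan2(2 Gxz, Gxx - Gzz); when Gxx = Gzz the convention is
    chi_G = +/- pi/4 with the sign of Gxz. tan2chi is reported as
    2 Gxz / (Gxx - Gzz) when defined, else the tangent of 2 chi_G limit.
    """
    G = g.G
    gxx, gzz, gxz = G[0, 0], G[2, 2], G[0, 2]
    chi = 0.5 * np.arctan2(2.0 * gxz, gxx - gzz)
    tan2chi = np.tan(2.0 * chi)
    g.chi_G = float(chi)
    g.tan2chi = float(tan2chi)
    if Wi is not None:
        if Wi <= 0:
            raise CombflowError("alignment: orientation resistance needs Wi > 0")
        g.mG = float(Wi * tan2chi)
    return g


def pdf(samples, bins=50):
    """Normalized probability density of a series of magnitudes.

    Returns (bin_centers, density); the density integrates to one over the
    binned support.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise CombflowError("pdf: empty series")
    dens, edges = np.histogram(samples, bins=bins, density=True)
    return 0.5 * (edges[1:] + edges[:-1]), dens


def fully_stretched_length(series, q: float = 0.01) -> float:
    """Mean of the top-q fraction of |Rete| samples — the operational
    definition of the fully stretched state (default: top 1%)."""
    x = np.sort(np.asarray(series, dtype=float))
    if x.size < int(np.ceil(1.0 / q)):
        raise CombflowError(
            f"fully_stretched_length: need at least {int(np.ceil(1.0 / q))} samples"
        )
    k = max(1, int(np.floor(q * x.size)))
    return float(np.mean(x[-k:]))
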