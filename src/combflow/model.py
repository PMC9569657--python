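"""Bead-spring comb polymer: topology, potentials, forces, initial states.

The comb consists of a linear backbone of ``Lb`` beads carrying ``Na`` linear
arms of ``La`` beads each, grafted at evenly spaced backbone beads, for a total
of N = Lb + Na*La beads. Excluded volume acts between every bead pair through
the purely repulsive WCA potential (Lennard-Jones truncated at 2^(1/6) sigma);
bonded neighbours are additionally held by a finitely extensible nonlinear
elastic (FENE) spring that diverges at the maximum bond length ``l0``. With the
defaults K = 30 eps/sigma^2 and l0 = 1.5 sigma the combined bond potential has
a steep single minimum near 0.96 sigma, which prevents chain crossing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .box import ShearBox
from .errors import BrokenBondError, PlacementError, TopologyError

#: WCA cutoff radius in units of sigma.
WCA_CUTOFF = 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class ModelParams:
    """Interaction parameters of the bead-spring model (MPCD units).

    epsilon and sigma set the energy and length scales; ``l0`` is the maximum
    FENE extension, ``K`` the FENE spring constant, ``monomer_mass`` the bead
    mass M in units of the solvent mass m. ``shift_wca`` selects the standard
    energy shift (+epsilon inside the cutoff) that makes the WCA energy
    continuous at r = 2^(1/6) sigma.
    """

    epsilon: float = 1.0
    sigma: float = 1.0
    l0: float = 1.5
    K: float = 30.0
    monomer_mass: float = 10.0
    shift_wca: bool = True

    def __post_init__(self):
        for name in ("epsilon", "sigma", "l0", "K", "monomer_mass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ModelParams.{name} must be positive")


@dataclass(frozen=True)
class CombTopology:
    """Bead/bond/graft structure of one comb polymer.

    Beads 0..Lb-1 are the backbone; arm k occupies the contiguous index range
    ``Lb + k*La .. Lb + (k+1)*La - 1``, its first bead bonded to one backbone
    bead. ``graft_map`` maps each grafted backbone index to the arm-root bead
    indices attached there.
    """

    Lb: int
    La: int
    Na: int
    bonds: np.ndarray = field(repr=False)  # (n_bonds, 2) int
    graft_map: dict = field(repr=False)

    @property
    def n_beads(self) -> int:
        return self.Lb + self.Na * self.La

    @property
    def backbone(self) -> np.ndarray:
        return np.arange(self.Lb)

    def arm(self, k: int) -> np.ndarray:
        """Bead indices of arm k, root first."""
        if not 0 <= k < self.Na or self.La == 0:
            raise IndexError(f"no arm {k}")
        start = self.Lb + k * self.La
        return np.arange(start, start + self.La)

    @property
    def species(self) -> np.ndarray:
        """Per-bead species labels: 'B' for backbone, 'A' for arm beads."""
        return np.array(["B"] * self.Lb + ["A"] * (self.Na * self.La))


def graft_indices(Lb: int, Na: int) -> np.ndarray:
    """Evenly spaced backbone indices carrying one arm root each."""
    if Na == 0:
        return np.array([], dtype=int)
    if Na == 1:
        return np.array([int(round((Lb - 1) / 2))])
    return np.round(np.arange(Na) * (Lb - 1) / (Na - 1)).astype(int)


def build_comb(Lb: int, La: int, Na: int) -> CombTopology:
    """Construct the comb topology (deterministic, no randomness).

    ``La = 0`` or ``Na = 0`` yields the bare backbone (a linear chain).
    Raises TopologyError for negative counts or Na > Lb (each backbone bead
    can carry at most one arm).
    """
    if Lb < 1 or La < 0 or Na < 0:
        raise TopologyError(f"invalid counts Lb={Lb}, La={La}, Na={Na}")
    if Na > Lb:
        raise TopologyError(f"cannot graft Na={Na} arms on Lb={Lb} backbone beads")
    if La == 0:
        Na = 0
    bonds = [(i, i + 1) for i in range(Lb - 1)]
    graft_map: dict[int, list[int]] = {}
    grafts = graft_indices(Lb, Na)
    for k in range(Na):
        root = Lb + k * La
        bonds.append((int(grafts[k]), root))
        graft_map.setdefault(int(grafts[k]), []).append(root)
        for j in range(La - 1):
            bonds.append((root + j, root + j + 1))
    bond_arr = (
        np.array(bonds, dtype=int) if bonds else np.empty((0, 2), dtype=int)
    )
    return CombTopology(Lb=Lb, La=La, Na=Na, bonds=bond_arr, graft_map=graft_map)


# ---------------------------------------------------------------------------
# Potentials
# ---------------------------------------------------------------------------

def wca_pair_energy(r, params: ModelParams = ModelParams()):
    """WCA (truncated, purely repulsive LJ) pair energy at separation r.

    Zero beyond the cutoff 2^(1/6) sigma; with ``shift_wca`` the energy is
    shifted by +epsilon inside the cutoff so it vanishes continuously there.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("wca_pair_energy: r must be positive (overlapping centers)")
    sr6 = (params.sigma / r) ** 6
    u = 4.0 * params.epsilon * (sr6 * sr6 - sr6)
    if params.shift_wca:
        u = u + params.epsilon
    u = np.where(r <= WCA_CUTOFF * params.sigma, u, 0.0)
    return u if u.ndim else float(u)


def fene_bond_energy(r, params: ModelParams = ModelParams()):
    """FENE bond energy -(K l0^2 / 2) ln(1 - (r/l0)^2), valid on 0 <= r < l0."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("fene_bond_energy: r must be nonnegative")
    if np.any(r >= params.l0):
        raise BrokenBondError(-1, -1, -1, float(np.max(r)), params.l0)
    x = r / params.l0
    u = -0.5 * params.K * params.l0**2 * np.log1p(-(x * x))
    return u if u.ndim else float(u)


def _wca_force_over_r(r2: np.ndarray, params: ModelParams) -> np.ndarray:
    """|F|/r for the WCA force at squared separations r2 (0 beyond cutoff)."""
    sig2 = params.sigma**2
    inside = r2 <= (WCA_CUTOFF**2) * sig2
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        sr2 = sig2 / r2
        sr6 = sr2 * sr2 * sr2
        f = 24.0 * params.epsilon * (2.0 * sr6 * sr6 - sr6) / r2
    return np.where(inside, f, 0.0)


def _fene_force_over_r(r2: np.ndarray, params: ModelParams) -> np.ndarray:
    """|F|/r for the FENE spring (attractive, so the value is negative)."""
    return -params.K / (1.0 - r2 / params.l0**2)


def bond_potential_minimum(params: ModelParams = ModelParams()) -> float:
    """Location of the single minimum of the combined FENE+WCA bond potential."""
    def total_force_over_r(r):
        r2 = np.asarray(r) ** 2
        return float(_wca_force_over_r(r2, params) + _fene_force_over_r(r2, params))

    hi = min(WCA_CUTOFF * params.sigma, 0.999 * params.l0)
    return brentq(total_force_over_r, 0.5 * params.sigma, hi)


# ---------------------------------------------------------------------------
# Forces
# ---------------------------------------------------------------------------

def _pair_table(n: int):
    iu = np.triu_indices(n, k=1)
    return iu[0], iu[1]


def pairwise_terms(
    positions: np.ndarray,
    topology: CombTopology,
    params: ModelParams,
    box: ShearBox | None = None,
):
    """Per-pair separation vectors and central forces for all interacting pairs.

    Returns ``(i, j, rij, fij)`` where ``rij = r_i - r_j`` (minimum image if a
    box is given) and ``fij`` is the force exerted on bead i by bead j. WCA
    acts on every pair; bonded pairs feel the FENE spring in addition.
    Raises BrokenBondError if any bond reaches l0.
    """
    n = len(positions)
    i, j = _pair_table(n)
    d = positions[i] - positions[j]
    if box is not None:
        d = box.minimum_image(d)
    r2 = np.einsum("ij,ij->i", d, d)
    f_over_r = _wca_force_over_r(r2, params)
    if len(topology.bonds):
        bi, bj = topology.bonds[:, 0], topology.bonds[:, 1]
        # map bond (bi, bj) with bi<bj to its row in the upper-triangle table
        lo = np.minimum(bi, bj)
        hi = np.maximum(bi, bj)
        flat = lo * (2 * n - lo - 1) // 2 + (hi - lo - 1)
        br2 = r2[flat]
        broken = br2 >= params.l0**2
        if np.any(broken):
            b = int(np.argmax(broken))
            raise BrokenBondError(
                b, int(lo[b]), int(hi[b]), float(np.sqrt(br2[b])), params.l0
            )
        f_over_r = f_over_r.copy()
        np.add.at(f_over_r, flat, _fene_force_over_r(br2, params))
    fij = f_over_r[:, None] * d
    return i, j, d, fij


def compute_polymer_forces(
    positions: np.ndarray,
    topology: CombTopology,
    params: ModelParams,
    box: ShearBox | None = None,
) -> np.ndarray:
    """Per-bead force vectors from WCA excluded volume plus FENE bonds.

    Forces are pairwise central, so they sum to zero exactly (Newton's third
    law) up to floating-point rounding.
    """
    if not np.all(np.isfinite(positions)):
        raise ValueError("compute_polymer_forces: non-finite positions")
    n = len(positions)
    forces = np.zeros((n, 3))
    if n < 2:
        return forces
    i, j, _, fij = pairwise_terms(positions, topology, params, box)
    np.add.at(forces, i, fij)
    np.subtract.at(forces, j, fij)
    return forces


def polymer_potential_energy(
    positions: np.ndarray,
    topology: CombTopology,
    params: ModelParams,
    box: ShearBox | None = None,
) -> float:
    """Total WCA + FENE potential energy of one configuration."""
    n = len(positions)
    if n < 2:
        return 0.0
    i, j = _pair_table(n)
    d = positions[i] - positions[j]
    if box is not None:
        d = box.minimum_image(d)
    r = np.sqrt(np.einsum("ij,ij->i", d, d))
    u = float(np.sum(wca_pair_energy(r, params)))
    if len(topology.bonds):
        bd = positions[topology.bonds[:, 0]] - positions[topology.bonds[:, 1]]
        if box is not None:
            bd = box.minimum_image(bd)
        br = np.linalg.norm(bd, axis=1)
        u += float(np.sum(fene_bond_energy(br, params)))
    return u


# ---------------------------------------------------------------------------
# Initial configurations
# ---------------------------------------------------------------------------

def _placement_order(topology: CombTopology):
    """(bead, parent) pairs in an order where the parent is already placed."""
    order = [(0, None)]
    order += [(i, i - 1) for i in range(1, topology.Lb)]
    for k in range(topology.Na):
        arm = topology.arm(k)
        graft = [g for g, roots in topology.graft_map.items() if arm[0] in roots][0]
        order.append((int(arm[0]), graft))
        order += [(int(arm[j]), int(arm[j - 1])) for j in range(1, topology.La)]
    return order


def init_polymer_configuration(
    topology: CombTopology,
    box: ShearBox,
    seed: int,
    params: ModelParams = ModelParams(),
    kBT: float = 1.0,
    bond_length: float = 0.97,
    min_separation: float = 0.85,
    max_trials: int = 200,
    max_restarts: int = 50,
):
    """Grow a self-avoiding initial comb configuration and thermal velocities.

    Beads are placed one by one at distance ``bond_length`` (sigma) from their
    bonded parent in a random direction, rejecting any placement closer than
    ``min_separation`` to a previously placed non-bonded bead (minimum image).
    On a dead end the grower backtracks a few beads; after ``max_restarts``
    full restarts it raises PlacementError (try a larger box). Velocities are
    Maxwellian at ``kBT`` for mass M with the net momentum removed. The same
    seed reproduces the same configuration exactly.
    """
    rng = np.random.default_rng(seed)
    n = topology.n_beads
    order = _placement_order(topology)
    b = bond_length * params.sigma
    for _ in range(max_restarts):
        pos = np.empty((n, 3))
        placed = np.zeros(n, dtype=bool)
        idx = 0
        stuck = False
        budget = 20 * len(order)  # total placement attempts this restart
        while idx < len(order):
            budget -= 1
            if budget < 0:
                stuck = True
                break
            bead, parent = order[idx]
            if parent is None:
                pos[bead] = box.L / 2.0
                placed[bead] = True
                idx += 1
                continue
            ok = False
            for _ in range(max_trials):
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                cand = pos[parent] + b * u
                others = placed.copy()
                others[parent] = False
                if others.any():
                    d = box.minimum_image(cand - pos[others])
                    if np.min(np.einsum("ij,ij->i", d, d)) < min_separation**2:
                        continue
                pos[bead] = cand
                placed[bead] = True
                ok = True
                break
            if ok:
                idx += 1
            else:
                # backtrack up to 3 beads and retry from there
                back = min(3, idx - 1)
                if back <= 0:
                    stuck = True
                    break
                for _ in range(back):
                    idx -= 1
                    placed[order[idx][0]] = False
        if not stuck and idx == len(order):
            vel = rng.normal(
                scale=np.sqrt(kBT / params.monomer_mass), size=(n, 3)
            )
            vel -= vel.mean(axis=0)
            return pos, vel
    raise PlacementError(
        f"could not place {n} beads in box L={box.L}; try a larger box"
    )
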