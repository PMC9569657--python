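"""Comb topology, WCA/FENE potentials, forces and initial configurations."""

import numpy as np
import pytest

from combflow import (
    BrokenBondError,
    ModelParams,
    PlacementError,
    ShearBox,
    TopologyError,
    WCA_CUTOFF,
    bond_potential_minimum,
    build_comb,
    compute_polymer_forces,
    fene_bond_energy,
    init_polymer_configuration,
    polymer_potential_energy,
    wca_pair_energy,
)
from combflow.model import graft_indices


@pytest.mark.parametrize(
    "Lb,La,Na,n_beads,n_bonds",
    [
        (20, 20, 20, 420, 419),  # dense comb: N = Lb + Na*La
        (20, 0, 0, 20, 19),  # bare backbone
        (1, 0, 0, 1, 0),  # single bead
        (20, 5, 4, 40, 39),  # sparse grafting
    ],
)
def test_build_comb_counts(Lb, La, Na, n_beads, n_bonds):
    topo = build_comb(Lb, La, Na)
    assert topo.n_beads == n_beads
    assert len(topo.bonds) == n_bonds


def test_comb_structure_invariants():
    topo = build_comb(10, 3, 5)
    # every arm is a simple path of La beads with its root bonded to exactly
    # one backbone bead
    bonds = {tuple(sorted(b)) for b in topo.bonds.tolist()}
    for k in range(topo.Na):
        arm = topo.arm(k)
        for a, b in zip(arm[:-1], arm[1:]):
            assert (a, b) in bonds
        root_links = [b for b in bonds if arm[0] in b and min(b) < topo.Lb]
        assert len(root_links) == 1
    # graft points evenly spaced
    g = graft_indices(10, 5)
    assert np.all(np.diff(g) >= 2) and g[0] == 0 and g[-1] == 9


def test_build_comb_errors():
    with pytest.raises(TopologyError):
        build_comb(5, 3, 6)  # more arms than backbone beads
    with pytest.raises(TopologyError):
        build_comb(0, 0, 0)
    with pytest.raises(TopologyError):
        build_comb(5, -1, 2)


def test_wca_energy_values(model_params):
    rc = WCA_CUTOFF
    assert wca_pair_energy(rc, model_params) == pytest.approx(0.0, abs=1e-12)
    assert wca_pair_energy(1.5, model_params) == 0.0
    # at r = sigma the 12- and 6-terms cancel: shifted energy is exactly eps
    assert wca_pair_energy(1.0, model_params) == pytest.approx(1.0, rel=1e-12)
    unshifted = ModelParams(shift_wca=False)
    assert wca_pair_energy(1.0, unshifted) == pytest.approx(0.0, abs=1e-12)
    # monotone decreasing inside the cutoff
    r = np.linspace(0.7, rc, 200)
    u = wca_pair_energy(r, model_params)
    assert np.all(np.diff(u) < 0)
    with pytest.raises(ValueError):
        wca_pair_energy(0.0, model_params)


def test_fene_energy_values(model_params):
    assert fene_bond_energy(0.0, model_params) == 0.0
    # frozen oracle: -(30*1.5^2/2) * ln(1 - (1/1.5)^2) = -33.75 ln(5/9)
    assert fene_bond_energy(1.0, model_params) == pytest.approx(
        19.837799940446516, rel=1e-12
    )
    assert fene_bond_energy(1.499999, model_params) > 300.0
    r = np.linspace(0.0, 1.45, 100)
    u = fene_bond_energy(r, model_params)
    assert np.all(u >= 0) and np.all(np.diff(u) > 0)
    with pytest.raises(BrokenBondError):
        fene_bond_energy(1.5, model_params)


def test_combined_bond_potential_single_minimum(model_params):
    rmin = bond_potential_minimum(model_params)
    assert 0.0 < rmin < model_params.l0
    r = np.linspace(0.85, 1.1, 400)
    u = wca_pair_energy(r, model_params) + fene_bond_energy(r, model_params)
    # single minimum: derivative changes sign exactly once
    signs = np.sign(np.diff(u))
    assert np.sum(np.abs(np.diff(signs)) > 0) == 1
    assert abs(r[np.argmin(u)] - rmin) < 2e-3


def test_bonded_pair_force_cancels_at_minimum(model_params):
    topo = build_comb(2, 0, 0)
    rmin = bond_potential_minimum(model_params)
    pos = np.array([[0.0, 0.0, 0.0], [rmin, 0.0, 0.0]])
    f = compute_polymer_forces(pos, topo, model_params)
    assert np.max(np.abs(f)) < 1e-8


def test_far_apart_unbonded_beads_have_zero_force(model_params):
    topo = build_comb(1, 0, 0)
    pos = np.array([[0.0, 0.0, 0.0]])
    assert np.allclose(compute_polymer_forces(pos, topo, model_params), 0.0)


@pytest.mark.parametrize("seed", range(5))
def test_forces_match_numerical_gradient(seed, model_params):
    """Analytic forces agree with central differences of the energy."""
    topo = build_comb(20, 0, 0)
    box = ShearBox(50.0, shear_offset=3.0)
    pos, _ = init_polymer_configuration(topo, box, seed=seed, params=model_params)
    f = compute_polymer_forces(pos, topo, model_params, box)
    assert np.max(np.abs(f.sum(axis=0))) < 1e-9  # Newton's third law
    eps = 1e-5
    rng = np.random.default_rng(seed)
    for bead in rng.choice(topo.n_beads, size=4, replace=False):
        for axis in range(3):
            pp = pos.copy()
            pp[bead, axis] += eps
            up = polymer_potential_energy(pp, topo, model_params, box)
            pp[bead, axis] -= 2 * eps
            um = polymer_potential_energy(pp, topo, model_params, box)
            fd = -(up - um) / (2 * eps)
            assert f[bead, axis] == pytest.approx(fd, abs=1e-6 + 1e-5 * abs(fd))


def test_energy_invariant_under_rigid_motion(model_params):
    topo = build_comb(10, 2, 5)
    box = ShearBox(60.0)
    pos, _ = init_polymer_configuration(topo, box, seed=11, params=model_params)
    u0 = polymer_potential_energy(pos, topo, model_params)
    assert polymer_potential_energy(pos + 3.7, topo, model_params) == pytest.approx(u0)
    th = 0.83
    R = np.array(
        [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
    )
    assert polymer_potential_energy(pos @ R.T, topo, model_params) == pytest.approx(u0)


def test_broken_bond_reports_offender(model_params):
    topo = build_comb(3, 0, 0)
    pos = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.6, 0, 0]])
    with pytest.raises(BrokenBondError) as exc:
        compute_polymer_forces(pos, topo, model_params)
    assert exc.value.pair == (1, 2)


def test_init_configuration_constraints_and_determinism(model_params):
    topo = build_comb(20, 20, 20)
    box = ShearBox(100.0)
    pos1, vel1 = init_polymer_configuration(topo, box, seed=5, params=model_params)
    pos2, vel2 = init_polymer_configuration(topo, box, seed=5, params=model_params)
    assert np.array_equal(pos1, pos2) and np.array_equal(vel1, vel2)
    # bond lengths inside the safe window
    d = box.minimum_image(pos1[topo.bonds[:, 0]] - pos1[topo.bonds[:, 1]])
    blen = np.linalg.norm(d, axis=1)
    assert np.all(blen > 0.7) and np.all(blen < 0.99 * model_params.l0)
    # no non-bonded pair closer than 0.85 sigma
    n = topo.n_beads
    iu = np.triu_indices(n, k=1)
    dist = np.linalg.norm(box.minimum_image(pos1[iu[0]] - pos1[iu[1]]), axis=1)
    bonded = {tuple(sorted(b)) for b in topo.bonds.tolist()}
    mask = np.array([(i, j) not in bonded for i, j in zip(*iu)])
    assert np.min(dist[mask]) >= 0.85
    # thermal velocities with zero net momentum
    assert np.allclose(vel1.sum(axis=0), 0.0, atol=1e-12)


def test_init_configuration_fails_in_tiny_box(model_params):
    topo = build_comb(20, 20, 20)
    with pytest.raises(PlacementError):
        init_polymer_configuration(
            topo, ShearBox(3.0), seed=0, params=model_params, max_restarts=2
        )
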