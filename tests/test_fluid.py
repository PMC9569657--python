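"""SRD solvent: streaming, collisions, thermostat, viscosity, shear profile."""

import numpy as np
import pytest
from scipy import stats

from combflow import (
    FluidParams,
    SolventState,
    cell_thermostat,
    collide,
    grid_shift_and_sort,
    initialize_solvent,
    kinetic_theory_viscosity,
    measure_velocity_profile,
    random_rotation_matrix,
    run_fluid,
    stream,
)
from combflow.fluid import relative_kinetic_temperature


def test_rotation_matrix_properties():
    rng = np.random.default_rng(0)
    R0 = random_rotation_matrix(0.0, rng)
    assert np.allclose(R0, np.eye(3), atol=1e-12)
    for _ in range(20):
        R = random_rotation_matrix(130.0, rng)
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)
        # trace = 1 + 2 cos(alpha); frozen: 1 + 2 cos(130 deg) = -0.285575
        assert np.trace(R) == pytest.approx(-0.2855752193730787, abs=1e-12)


def test_stream_literal_update():
    s = SolventState(
        positions=np.array([[0.0, 0, 0]]), velocities=np.array([[1.0, 0, 0]]), L=10.0
    )
    stream(s, 0.1)
    assert np.allclose(s.positions, [[0.1, 0, 0]])
    s2 = SolventState(
        positions=np.array([[2.0, 3, 4]]), velocities=np.zeros((1, 3)), L=10.0
    )
    stream(s2, 0.5)
    assert np.allclose(s2.positions, [[2.0, 3, 4]])


def test_stream_lees_edwards_crossing():
    """Hand-computed image rule: a particle leaving the top face re-enters at
    the bottom with vx reduced by gamma_dot*L and x shifted by the offset."""
    L, g = 10.0, 0.1
    s = SolventState(
        positions=np.array([[5.0, 5.0, 9.95]]),
        velocities=np.array([[2.0, 0.0, 1.0]]),
        L=L,
    )
    stream(s, 0.1, gamma_dot=g)
    # offset advanced to g*L*h = 0.1 before wrapping
    assert s.positions[0, 2] == pytest.approx(0.05)
    assert s.positions[0, 0] == pytest.approx(5.0 + 0.2 - 0.1)
    assert s.velocities[0, 0] == pytest.approx(2.0 - g * L)


def test_grid_shift_binning():
    pos = np.array([[1.2, 0.5, 0.5], [1.0, 0.5, 0.5], [7.5, 3.5, 9.9]])
    cells0 = grid_shift_and_sort(pos, 10.0, 1.0, shift=np.zeros(3))
    # zero shift equals plain binning: x=1.2 and x=1.0 both sit in x-cell 1
    assert cells0.cell_ids[0] == (1 * 10 + 0) * 10 + 0
    assert cells0.cell_ids[1] == (1 * 10 + 0) * 10 + 0
    # shift +a/2 moves the boundary particle to the neighbour cell:
    # (1.0 - 0.5)/a = 0.5 -> x-cell 0 (hand-binned)
    cells = grid_shift_and_sort(pos, 10.0, 1.0, shift=np.array([0.5, 0.0, 0.0]))
    assert cells.cell_ids[1] == 0
    assert cells.cell_ids[0] == 0  # (1.2-0.5)=0.7 -> cell 0 too
    # partition: every particle lands in exactly one cell
    assert cells.counts.sum() == len(pos)


def test_collide_single_particle_cell_unchanged():
    pos = np.array([[0.5, 0.5, 0.5]])
    cells = grid_shift_and_sort(pos, 4.0, 1.0, shift=np.zeros(3))
    v = np.array([[1.0, 2.0, 3.0]])
    out = collide(cells, v, 1.0, 130.0, np.random.default_rng(0))
    assert np.array_equal(out, v)


def test_collide_conserves_momentum_and_relative_energy():
    rng = np.random.default_rng(1)
    pos = rng.uniform(0, 1, size=(10, 3))  # all in one cell
    cells = grid_shift_and_sort(pos, 4.0, 4.0, shift=np.zeros(3))
    v = rng.normal(size=(10, 3))
    out = collide(cells, v, 1.0, 130.0, rng)
    assert np.allclose(out.sum(axis=0), v.sum(axis=0), atol=1e-12)
    vcm = v.mean(axis=0)
    e_before = np.sum((v - vcm) ** 2)
    e_after = np.sum((out - out.mean(axis=0)) ** 2)
    assert e_after == pytest.approx(e_before, rel=1e-12)


def test_collide_mixed_mass_center_of_mass_oracle():
    """9 solvent (m=1) + 1 monomer (M=10): the cell average is the
    mass-weighted mean, checked against an explicit hand-summed oracle."""
    rng = np.random.default_rng(2)
    pos = rng.uniform(0, 1, size=(10, 3))
    cells = grid_shift_and_sort(pos, 4.0, 4.0, shift=np.zeros(3))
    v = rng.normal(size=(10, 3))
    masses = np.array([1.0] * 9 + [10.0])
    # hand-summed weighted average
    vcm_oracle = np.zeros(3)
    for i in range(10):
        vcm_oracle += masses[i] * v[i]
    vcm_oracle /= masses.sum()
    out = collide(cells, v, masses, 130.0, rng)
    # momentum conservation implies the same weighted mean afterwards
    vcm_after = (masses[:, None] * out).sum(axis=0) / masses.sum()
    assert np.allclose(vcm_after, vcm_oracle, atol=1e-12)
    # relative speeds are preserved and all particles share one rotation
    # whose trace identifies the 130-degree angle
    vrel = v - vcm_oracle
    vrel_out = out - vcm_oracle
    assert np.allclose(
        np.linalg.norm(vrel_out, axis=1), np.linalg.norm(vrel, axis=1), atol=1e-10
    )
    R, *_ = np.linalg.lstsq(vrel, vrel_out, rcond=None)
    assert np.trace(R.T) == pytest.approx(1 + 2 * np.cos(np.deg2rad(130.0)), abs=1e-8)


def test_thermostat_preserves_momentum_and_pins_temperature():
    rng = np.random.default_rng(3)
    pos = rng.uniform(0, 2, size=(40, 3))
    cells = grid_shift_and_sort(pos, 2.0, 1.0, shift=np.zeros(3))
    v = rng.normal(scale=2.0, size=(40, 3))  # too hot
    out = cell_thermostat(cells, v, 1.0, 1.0, rng, mode="rescale")
    assert np.allclose(
        (out).sum(axis=0), v.sum(axis=0), atol=1e-12
    )  # relative-velocity scaling keeps momentum
    assert relative_kinetic_temperature(cells, out, 1.0) == pytest.approx(1.0)
    # mbs draws canonical energies: momentum still exact
    out2 = cell_thermostat(cells, v, 1.0, 1.0, rng, mode="mbs")
    assert np.allclose(out2.sum(axis=0), v.sum(axis=0), atol=1e-12)


def test_kinetic_theory_viscosity_closed_form():
    p = FluidParams()
    eta_kin, eta_coll = kinetic_theory_viscosity(p, parts=True)
    # alpha = 0: identity rotation, no collisional transport
    assert kinetic_theory_viscosity(FluidParams(alpha=0.0), parts=True)[1] == 0.0
    # doubling h doubles the kinetic part and halves the collisional part
    k2, c2 = kinetic_theory_viscosity(FluidParams(h=0.2), parts=True)
    assert k2 == pytest.approx(2 * eta_kin, rel=1e-12)
    assert c2 == pytest.approx(eta_coll / 2, rel=1e-12)


def test_equilibrium_temperature_and_maxwellian_marginals():
    """Long quiescent run: equipartition at kBT = 1 and Maxwellian velocity
    marginals (KS at the 1% level on >= 1e5 samples)."""
    res = run_fluid(
        FluidParams(),
        n_side=10,
        n_steps=700,
        seed=42,
        warmup=200,
        collect_velocities=120_000,
    )
    assert res.kBT == pytest.approx(1.0, abs=0.01)
    v = res.velocity_samples
    assert v.shape[0] * 3 >= 1e5
    for axis in range(3):
        ks = stats.kstest(v[:, axis], "norm", args=(0.0, 1.0))
        assert ks.pvalue > 0.01
    # no net flow: fitted vx(z) slope consistent with zero
    assert abs(res.profile.slope) < 5e-3


def test_velocity_profile_measurement():
    rng = np.random.default_rng(5)
    L, g = 10.0, 0.1
    frames = []
    for _ in range(20):
        pos = rng.uniform(0, L, size=(4000, 3))
        vel = rng.normal(size=(4000, 3))
        vel[:, 0] += g * (pos[:, 2] - L / 2)
        frames.append((pos, vel))
    prof = measure_velocity_profile(frames, L)
    assert prof.slope == pytest.approx(g, rel=0.05)
    # antisymmetric about the box centre in the Lees-Edwards frame
    assert np.allclose(prof.vx, -prof.vx[::-1], atol=0.05)


def test_galilean_invariance_under_boost():
    """A uniform velocity boost leaves cell-relative observables unchanged
    (the random grid shift prevents boost-dependent artefacts)."""
    p = FluidParams()
    rng = np.random.default_rng(6)
    state = initialize_solvent(8.0, p, rng)
    state.velocities[:, 0] += 2.0  # constant boost
    for _ in range(200):
        stream(state, p.h)
        cells = grid_shift_and_sort(state.positions, 8.0, 1.0, rng=rng)
        v = collide(cells, state.velocities, 1.0, p.alpha, rng)
        state.velocities = cell_thermostat(cells, v, 1.0, 1.0, rng, "mbs")
    cells = grid_shift_and_sort(state.positions, 8.0, 1.0, rng=rng)
    assert relative_kinetic_temperature(
        cells, state.velocities, 1.0
    ) == pytest.approx(1.0, abs=0.03)
    # the boost itself survives (momentum conservation)
    assert state.velocities[:, 0].mean() == pytest.approx(2.0, abs=0.05)
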