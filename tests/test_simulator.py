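"""Builders and Langevin dynamics on small, fast systems."""

import numpy as np
import pytest

from cgllps import simulator as sim
from cgllps.constants import KB
from cgllps.sequences import ProteinSequence
from cgllps.system import Configuration


@pytest.fixture(scope="module")
def toy_seq():
    return ProteinSequence("toy", "WGWGWGWGWG")


def test_slab_builder_geometry_and_overlaps(toy, toy_seq):
    cfg = sim.build_slab_configuration(
        toy, toy_seq, 6, cross_section=16.0, length=24.0, seed=1, occupied_fraction=0.25
    )
    assert cfg.n_beads == 60
    assert np.allclose(cfg.box, [4.0, 4.0, 24.0])
    # insertion restricted to the central quarter of the long axis
    assert cfg.positions[:, 2].min() >= 9.0 - 1e-9
    assert cfg.positions[:, 2].max() <= 15.0 + 1e-9
    # no non-bonded pair below the overlap threshold
    bonds = {tuple(b) for b in map(tuple, cfg.bonds())}
    sigma = toy.residues["G"].sigma
    for i in range(cfg.n_beads):
        for j in range(i + 1, cfg.n_beads):
            if (i, j) in bonds:
                continue
            d = cfg.positions[i] - cfg.positions[j]
            d -= cfg.box * np.round(d / cfg.box)
            assert np.linalg.norm(d) >= 0.7 * sigma - 1e-9


def test_slab_builder_bond_lengths(toy, toy_seq):
    cfg = sim.build_slab_configuration(toy, toy_seq, 4, 16.0, 24.0, seed=2)
    bonds = cfg.bonds()
    d = cfg.positions[bonds[:, 0]] - cfg.positions[bonds[:, 1]]
    d -= cfg.box * np.round(d / cfg.box)
    assert np.allclose(np.linalg.norm(d, axis=1), toy.bond_r0_nm, atol=1e-9)


def test_bulk_builder_reaches_target_density(toy, toy_seq):
    cfg = sim.build_bulk_configuration(
        toy, toy_seq, 4, target_density=0.05, seed=2, relax_temperature=150.0
    )
    assert sim.mass_density(cfg, toy) == pytest.approx(0.05, rel=0.011)


def test_mass_density_hand_value(toy):
    # 2 beads of 100 g/mol in 10 nm^3
    cfg = Configuration(
        np.array([[0.5, 0.5, 0.5], [1.5, 1.5, 1.5]]),
        np.array([1.0, 2.0, 5.0]),
        np.array([0, 1]),
        np.array(["G", "G"]),
    )
    from cgllps.constants import MASS_DENSITY_TO_G_CM3

    assert sim.mass_density(cfg, toy) == pytest.approx(20.0 * MASS_DENSITY_TO_G_CM3)


def test_maxwell_boltzmann_statistics():
    rng = np.random.default_rng(0)
    masses = np.full(4000, 80.0)
    v = sim.maxwell_boltzmann_velocities(masses, 300.0, rng)
    assert sim.kinetic_temperature(v, masses) == pytest.approx(300.0, rel=0.05)
    assert np.abs(v.mean(axis=0)).max() < 3 * np.sqrt(KB * 300.0 / 80.0 / 4000)


def test_zero_step_run_returns_initial_state(toy, toy_seq):
    cfg = sim.build_slab_configuration(toy, toy_seq, 2, 16.0, 24.0, seed=3)
    settings = sim.SimulationSettings(temperature=150.0, n_steps=0, seed=1)
    traj, stress, energies = sim.run_langevin(cfg, toy, settings)
    assert len(traj) == 1
    assert np.allclose(traj.frames[0].positions, cfg.positions)


def test_run_is_deterministic_for_fixed_seed(toy, toy_seq):
    cfg = sim.build_slab_configuration(toy, toy_seq, 3, 16.0, 24.0, seed=4)
    settings = sim.SimulationSettings(
        temperature=150.0, n_steps=500, seed=9, stress_stride=50
    )
    t1, s1, e1 = sim.run_langevin(cfg, toy, settings)
    t2, s2, e2 = sim.run_langevin(cfg, toy, settings)
    assert np.array_equal(t1.frames[-1].positions, t2.frames[-1].positions)
    assert np.array_equal(s1.sxy, s2.sxy)
    assert e1.equals(e2)


def test_different_seeds_diverge(toy, toy_seq):
    cfg = sim.build_slab_configuration(toy, toy_seq, 3, 16.0, 24.0, seed=4)
    a = sim.SimulationSettings(temperature=150.0, n_steps=200, seed=1)
    b = sim.SimulationSettings(temperature=150.0, n_steps=200, seed=2)
    ta, _, _ = sim.run_langevin(cfg, toy, a)
    tb, _, _ = sim.run_langevin(cfg, toy, b)
    assert not np.allclose(ta.frames[-1].positions, tb.frames[-1].positions)


def test_nve_energy_conservation_harmonic_dimer(toy):
    # two bonded beads, far from any nonbonded cutoff effects: velocity
    # Verlet must conserve E to O(dt^2)
    r0 = toy.bond_r0_nm
    cfg = Configuration(
        np.array([[2.0, 2.0, 2.0], [2.0, 2.0, 2.0 + r0 + 0.05]]),
        np.array([8.0, 8.0, 8.0]),
        np.array([0, 0]),
        np.array(["G", "G"]),
    )
    cfg.velocities = np.zeros((2, 3))
    settings = sim.SimulationSettings(
        temperature=150.0, n_steps=2000, timestep=2.0, damping=None,
        seed=0, energy_stride=10, stress_stride=0,
    )
    _, _, en = sim.run_langevin(cfg, toy, settings)
    tot = en["potential"] + en["kinetic"]
    assert tot.std() < 1e-4 * max(abs(tot.iloc[0]), 1.0)


def test_nve_drift_bounded_many_body(toy, toy_seq):
    # truncated potentials leak energy at cutoff crossings; the drift must
    # stay small over a short run
    cfg = sim.build_bulk_configuration(toy, toy_seq, 4, 0.05, seed=2, relax_temperature=150.0)
    eq = sim.SimulationSettings(temperature=150.0, n_steps=2000, seed=7, stress_stride=0, energy_stride=0)
    traj, _, _ = sim.run_langevin(cfg, toy, eq)
    settings = sim.SimulationSettings(
        temperature=150.0, n_steps=5000, timestep=2.0, damping=None,
        seed=0, energy_stride=100, stress_stride=0,
    )
    _, _, en = sim.run_langevin(traj.frames[-1], toy, settings)
    tot = en["potential"] + en["kinetic"]
    assert abs(tot.iloc[-1] - tot.iloc[0]) < 0.02 * abs(tot.iloc[0])


def test_thermostat_reaches_target_temperature(toy, toy_seq):
    cfg = sim.build_slab_configuration(toy, toy_seq, 10, 16.0, 24.0, seed=5, occupied_fraction=0.5)
    # start cold: velocities all zero
    cfg.velocities = np.zeros((cfg.n_beads, 3))
    settings = sim.SimulationSettings(
        temperature=150.0, n_steps=8000, seed=3, energy_stride=100, stress_stride=0
    )
    _, _, en = sim.run_langevin(cfg, toy, settings)
    late = en["temperature"].iloc[len(en) // 2 :]
    assert late.mean() == pytest.approx(150.0, rel=0.08)


def test_virial_stress_ideal_gas_limit(toy):
    # widely separated beads: stress is purely kinetic, trace/3 = N kB T / V
    rng = np.random.default_rng(1)
    n = 64
    box = np.array([40.0, 40.0, 40.0])
    pos = (np.indices((4, 4, 4)).reshape(3, -1).T + 0.5) * 10.0
    cfg = Configuration(pos, box, np.arange(n), np.array(["G"] * n))
    masses = cfg.masses(toy.residue_masses)
    vel = sim.maxwell_boltzmann_velocities(masses, 200.0, rng)
    s = sim.virial_stress(cfg, vel, toy)
    from cgllps.constants import PRESSURE_KJ_NM3_TO_BAR

    p_expected = n * KB * sim.kinetic_temperature(vel, masses) / box.prod() * PRESSURE_KJ_NM3_TO_BAR
    assert np.trace(s) / 3.0 == pytest.approx(p_expected, rel=1e-10)
    # off-diagonal consistency: symmetric tensor
    assert np.allclose(s, s.T)


def test_nan_positions_raise(toy, toy_seq):
    cfg = sim.build_slab_configuration(toy, toy_seq, 2, 16.0, 24.0, seed=6)
    cfg.positions[0] = cfg.positions[1]  # perfect overlap -> divergent force
    settings = sim.SimulationSettings(temperature=150.0, n_steps=10, seed=0)
    with pytest.raises(sim.SimulationError):
        sim.run_langevin(cfg, toy, settings)


def test_settings_validation():
    with pytest.raises(ValueError):
        sim.SimulationSettings(temperature=300.0, n_steps=1, timestep=0.0)
    with pytest.raises(ValueError):
        sim.SimulationSettings(temperature=300.0, n_steps=1, damping=-1.0)
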