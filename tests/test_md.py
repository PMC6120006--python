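"""Rigid-body integrator, thermostat, force providers, and run contracts."""

import numpy as np
import pytest

from cgblob.geometry import Configuration, fcc_configuration, kinetic_temperature
from cgblob.md import (AllAtomProvider, GeneralCGProvider, RadialCGProvider,
                       SimulationConfig, Trajectory, make_provider, run,
                       thermostat_rescale)
from cgblob.quaternion import normalize, random_quaternion
from cgblob.series import TruncationScheme
from cgblob.units import KB


def _pair_config(template, sep, box=200.0, vrel=0.3, seed=0):
    rng = np.random.default_rng(seed)
    pos = np.array([[box / 2 - sep / 2, box / 2, box / 2],
                    [box / 2 + sep / 2, box / 2, box / 2]])
    vel = np.array([[vrel / 2, 0.05, 0.0], [-vrel / 2, -0.05, 0.0]])
    quats = normalize(random_quaternion(rng, 2))
    omega = rng.normal(0, 0.05, (2, 3))
    return Configuration(template, box, pos, vel, quats, omega)


def _nve_config(pot, engine, order=3, steps=2000, dt=2.0, cutoff=60.0):
    return SimulationConfig(potential=pot, engine=engine, order=order,
                            timestep=dt, n_steps_equil=0, n_steps_prod=steps,
                            temperature=300.0, thermostat_interval_equil=0,
                            thermostat_interval_prod=0, cutoff=cutoff,
                            frame_stride=50, velocity_stride=50)


class TestThermostat:
    def test_rescale_hits_target_exactly(self, united_atom):
        cfg = fcc_configuration(32, 1.219, united_atom, 900.0, seed=1)
        cfg.velocities *= 1.7  # detune
        thermostat_rescale(cfg, 1529.0)
        assert kinetic_temperature(cfg) == pytest.approx(1529.0, rel=1e-12)

    def test_rescale_preserves_zero_momentum(self, united_atom):
        cfg = fcc_configuration(32, 1.219, united_atom, 900.0, seed=1)
        thermostat_rescale(cfg, 1529.0)
        assert np.abs(cfg.velocities.sum(axis=0)).max() < 1e-10

    def test_run_average_temperature_within_one_percent(self, united_atom,
                                                        cg3_effective):
        cfg = SimulationConfig(potential=cg3_effective, engine="cg", order=3,
                               timestep=5.0, n_steps_equil=400, n_steps_prod=1500,
                               temperature=1529.0, thermostat_interval_equil=10,
                               thermostat_interval_prod=20, frame_stride=5,
                               velocity_stride=100, seed=4)
        init = fcc_configuration(32, 1.219, united_atom, 1529.0, seed=4)
        traj = run(cfg, init)
        assert abs(traj.temperatures.mean() - 1529.0) / 1529.0 < 0.01


class TestProviders:
    def test_newtons_third_law_all_providers(self, c60, united_atom,
                                             atomic_morse, cg3_effective):
        init = fcc_configuration(32, 1.219, united_atom, 1529.0, seed=7)
        sch = TruncationScheme.up_to(3)
        providers = [
            RadialCGProvider(united_atom, cg3_effective, sch, 20.0, init.box_edge),
            GeneralCGProvider(c60, atomic_morse, sch, 20.0, init.box_edge),
            AllAtomProvider(c60, atomic_morse, 12.3, init.box_edge),
        ]
        quats = normalize(random_quaternion(np.random.default_rng(0), 32))
        for prov in providers:
            f, tq, e = prov.compute(init.positions, quats)
            scale = max(np.abs(f).max(), 1e-12)
            assert np.abs(f.sum(axis=0)).max() / scale < 1e-9

    def test_radial_and_general_cg_agree_for_c60(self, c60, cg3_effective):
        sch = TruncationScheme.up_to(3)
        init = _pair_config(c60, 11.0)
        rp = RadialCGProvider(c60, cg3_effective, sch, 40.0, init.box_edge)
        gp = GeneralCGProvider(c60, cg3_effective, sch, 40.0, init.box_edge)
        f1, t1, e1 = rp.compute(init.positions, init.orientations)
        f2, t2, e2 = gp.compute(init.positions, init.orientations)
        # the radial path subtracts the cutoff shift; remove it for comparison
        shift = rp.shift
        assert e1 + shift == pytest.approx(e2, rel=1e-12, abs=1e-12)
        np.testing.assert_allclose(f1, f2, atol=1e-12)
        assert np.abs(t2).max() < 1e-9  # isotropic cage: no torques

    def test_point_blob_cg_equals_allatom_engine(self, united_atom, cg3_effective):
        """Cross-engine equivalence on a 32-particle toy: a point blob run
        through the CG series equals the bare pair potential engine."""
        init = fcc_configuration(32, 1.219, united_atom, 1529.0, seed=3)
        sch = TruncationScheme.up_to(3)
        rp = RadialCGProvider(united_atom, cg3_effective, sch, 20.0, init.box_edge)
        ap = AllAtomProvider(united_atom, cg3_effective, 20.0, init.box_edge)
        f1, _, e1 = rp.compute(init.positions, init.orientations)
        f2, _, e2 = ap.compute(init.positions, init.orientations)
        np.testing.assert_allclose(f1, f2, rtol=1e-9, atol=1e-9)
        assert e1 == pytest.approx(e2, rel=1e-9)

    def test_make_provider_selects_radial_for_isotropic(self, c60, united_atom,
                                                        make_blob, cg3_effective):
        cfg = SimulationConfig(potential=cg3_effective, engine="cg", order=3)
        assert isinstance(make_provider(cfg, c60, 100.0), RadialCGProvider)
        assert isinstance(make_provider(cfg, united_atom, 100.0), RadialCGProvider)
        assert isinstance(make_provider(cfg, make_blob(5, seed=2), 100.0),
                          GeneralCGProvider)


class TestIntegration:
    def test_free_molecules_move_uniformly(self, united_atom, cg3_effective):
        # two molecules far outside the cutoff: straight-line motion
        init = _pair_config(united_atom, 150.0, box=400.0, vrel=2.0)
        cfg = _nve_config(cg3_effective, "cg", steps=500, cutoff=20.0)
        traj = run(cfg, init)
        assert np.allclose(traj.energies, 0.0, atol=1e-12)
        assert traj.temperatures.std() < 1e-9

    def test_free_spherical_top_keeps_spin(self, c60, cg3_effective):
        init = _pair_config(c60, 150.0, box=400.0, vrel=0.0, seed=5)
        init.angular_velocities = np.array([[0.0, 0.0, 0.8], [0.2, 0.0, 0.0]])
        cfg = _nve_config(cg3_effective, "cg", steps=1000, cutoff=20.0)
        traj = run(cfg, init)
        # kinetic temperature (translation + rotation) constant for free rotors
        assert traj.temperatures.std() / traj.temperatures.mean() < 1e-8

    @pytest.mark.parametrize("engine", ["cg", "allatom"])
    def test_short_nve_energy_drift(self, c60, united_atom, atomic_morse,
                                    cg3_effective, engine):
        # the CG model of C60 is the united-atom blob + effective Morse;
        # the all-atom engine uses the cage + atomic Morse
        if engine == "cg":
            pot, template = cg3_effective, united_atom
        else:
            pot, template = atomic_morse, c60
        init = _pair_config(template, 10.0)
        cfg = _nve_config(pot, engine, steps=2000)
        traj = run(cfg, init)
        dof = 12 if engine == "allatom" else 6  # point blobs do not rotate
        etot = traj.energies + 0.5 * dof * KB * traj.temperatures
        drift = etot.max() - etot.min()
        assert drift < 1e-3 * 6.37  # well depth of the effective potential

    def test_momentum_conserved_in_smoke_run(self, united_atom, cg3_effective):
        init = fcc_configuration(32, 1.219, united_atom, 1529.0, seed=9)
        cfg = SimulationConfig(potential=cg3_effective, engine="cg", order=3,
                               timestep=5.0, n_steps_equil=0, n_steps_prod=1000,
                               temperature=1529.0, thermostat_interval_equil=0,
                               thermostat_interval_prod=0, frame_stride=100,
                               velocity_stride=100)
        traj = run(cfg, init)
        m = united_atom.molar_mass
        p = m * traj.velocities[-1].sum(axis=0)
        pscale = m * np.abs(traj.velocities[-1]).max()
        assert np.abs(p).max() / pscale < 1e-8

    def test_same_seed_gives_identical_trajectories(self, united_atom,
                                                    cg3_effective):
        def one():
            cfg = SimulationConfig(potential=cg3_effective, engine="cg", order=3,
                                   timestep=5.0, n_steps_equil=100,
                                   n_steps_prod=300, temperature=1529.0,
                                   frame_stride=10, velocity_stride=10, seed=21)
            init = fcc_configuration(32, 1.219, united_atom, 1529.0, seed=21)
            return run(cfg, init)

        a, b = one(), one()
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.velocities, b.velocities)
        np.testing.assert_array_equal(a.energies, b.energies)

    def test_trajectory_roundtrip(self, tmp_path, united_atom, cg3_effective):
        cfg = SimulationConfig(potential=cg3_effective, engine="cg", order=3,
                               timestep=5.0, n_steps_equil=0, n_steps_prod=100,
                               temperature=1529.0, frame_stride=10,
                               velocity_stride=10)
        init = fcc_configuration(32, 1.219, united_atom, 1529.0, seed=2)
        traj = run(cfg, init)
        path = tmp_path / "traj.npz"
        traj.save(path)
        back = Trajectory.load(path)
        np.testing.assert_array_equal(back.positions, traj.positions)
        assert back.metadata["engine"] == "cg"
        assert back.box_edge == traj.box_edge
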