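"""Integrators: limits, conservation laws, thermostats, tilt bookkeeping."""

import numpy as np
import pytest

import lowshear as ls


def _free_particle_state(edge=20.0):
    box = ls.BoxSpec.cubic(edge)
    pos = np.array([[5.0, 7.0, 3.0]])
    mom = np.array([[0.4, -0.3, 0.2]])
    return ls.PhasePoint(pos, mom, np.ones(1), box)


class TestIntegratorSpec:
    def test_mode_constraints(self):
        with pytest.raises(ValueError):
            ls.IntegratorSpec("sllod_nvt", 0.01)  # thermostat required
        with pytest.raises(ValueError):
            ls.IntegratorSpec("sllod_nve", 0.01,
                              thermostat=ls.ThermostatState(1.0))
        with pytest.raises(ValueError):
            ls.IntegratorSpec("equilibrium", 0.01, shear_rate=0.1)
        with pytest.raises(ValueError):
            ls.ThermostatState(-1.0)


class TestStep:
    def test_zero_shear_sllod_equals_equilibrium(self, dpd_ff,
                                                 dpd_thermal_state):
        """At zero shear the SLLOD equations reduce to plain NVE."""
        rng = ls.RandomStreamSpec(9)
        eq = ls.IntegratorSpec("equilibrium", 0.01)
        sl = ls.IntegratorSpec("sllod_nve", 0.01, shear_rate=0.0)
        a, pa, _ = ls.advance(dpd_thermal_state, dpd_ff, eq, rng, 50)
        b, pb, _ = ls.advance(dpd_thermal_state, dpd_ff, sl, rng, 50)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.momenta, b.momenta)
        np.testing.assert_array_equal(pa, pb)

    def test_free_particle_sllod_one_step(self, wca_ff):
        """Analytic one-step expansion for a particle with no neighbours."""
        state = _free_particle_state()
        dt, g = 1e-3, 0.2
        integ = ls.IntegratorSpec("sllod_nve", dt, shear_rate=g)
        new = ls.step(state, wca_ff, integ, ls.RandomStreamSpec(0))
        px, py = state.momenta[0, 0], state.momenta[0, 1]
        x, y = state.positions[0, 0], state.positions[0, 1]
        # p_y is force-free and unsheared; p_x loses g*p_y*dt exactly
        assert new.momenta[0, 1] == py
        assert new.momenta[0, 0] == pytest.approx(px - g * py * dt,
                                                  rel=1e-13)
        # x gains dt*(p_x/m + g*y) to first order in dt
        assert new.positions[0, 0] == pytest.approx(x + dt * (px + g * y),
                                                    abs=1e-6)
        assert new.positions[0, 1] == pytest.approx(y + dt * py, rel=1e-12)

    def test_deterministic_replay(self, dpd_ff, dpd_thermal_state):
        rng = ls.RandomStreamSpec(4)
        integ = ls.IntegratorSpec("sllod_nve", 0.01, shear_rate=1e-3)
        a, pa, _ = ls.advance(dpd_thermal_state, dpd_ff, integ, rng, 40)
        b, pb, _ = ls.advance(dpd_thermal_state, dpd_ff, integ, rng, 40)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(pa, pb)

    def test_blowup_detection(self, wca_ff):
        # two nearly-overlapping WCA particles with a huge timestep
        box = ls.BoxSpec.cubic(10.0)
        state = ls.PhasePoint(np.array([[5.0, 5.0, 5.0], [5.001, 5.0, 5.0]]),
                              np.zeros((2, 3)), np.ones(2), box)
        integ = ls.IntegratorSpec("equilibrium", 1e150)
        with pytest.raises(ValueError):
            ls.advance(state, wca_ff, integ, ls.RandomStreamSpec(0), 5)


class TestConservation:
    def test_wca_nve_energy_drift(self, wca_ff, wca_thermal_state):
        """Velocity-Verlet keeps the WCA total-energy drift tiny."""
        dt = 2.5e-3
        rng = ls.RandomStreamSpec(0)
        integ = ls.IntegratorSpec("equilibrium", dt)

        def total_energy(s):
            ke = 0.5 * np.sum(s.momenta ** 2 / s.masses[:, None])
            pe = ls.compute_all_forces(s, wca_ff, 0.0, rng,
                                       dt).potential_energy
            return ke + pe

        e0 = total_energy(wca_thermal_state)
        final, _, _ = ls.advance(wca_thermal_state, wca_ff, integ, rng,
                                 10_000)
        e1 = total_energy(final)
        assert abs(e1 - e0) / abs(e0) <= 1e-4

    def test_dpd_equilibrium_temperature(self, dpd_temp_series):
        """The DPD pair thermostat holds <T_kin> = 1 within 2%."""
        assert dpd_temp_series.mean() == pytest.approx(1.0, abs=0.02)

    def test_momentum_conserved_along_trajectory(self, dpd_ff,
                                                 dpd_thermal_state):
        final, _, _ = ls.advance(dpd_thermal_state, dpd_ff,
                                 ls.IntegratorSpec("equilibrium", 0.01),
                                 ls.RandomStreamSpec(21), 500)
        np.testing.assert_allclose(final.momenta.sum(axis=0),
                                   dpd_thermal_state.momenta.sum(axis=0),
                                   atol=1e-9)


class TestTiltBookkeeping:
    @pytest.mark.parametrize("g,n_steps", [(0.5, 100), (3.0, 400)])
    def test_strain_accounting_across_flips(self, wca_ff, g, n_steps):
        state = _free_particle_state(edge=5.0)
        state.positions[:] = [[2.0, 2.0, 2.0]]
        dt = 0.01
        integ = ls.IntegratorSpec("sllod_nve", dt, shear_rate=g)
        new, _, _ = ls.advance(state, wca_ff, integ, ls.RandomStreamSpec(0),
                               n_steps)
        total = n_steps * g * 5.0 * dt
        expected = total - round(total / 5.0) * 5.0
        assert new.box.tilt_xy == pytest.approx(expected, abs=1e-10)
        assert abs(new.box.tilt_xy) <= 2.5 + 1e-12

    def test_linear_velocity_profile(self, dpd_ff, dpd_thermal_state):
        """Sheared DPD sustains the linear profile: peculiar momenta stay
        unstructured in y, so the lab profile has slope gammadot."""
        g = 0.2
        integ = ls.IntegratorSpec("sllod_nve", 0.01, shear_rate=g)
        state = dpd_thermal_state
        rng = ls.RandomStreamSpec(31)
        # discard the transient, then accumulate binned peculiar velocities
        state, _, _ = ls.advance(state, dpd_ff, integ, rng, 500)
        edges = np.linspace(0, 5.0, 6)
        sums = np.zeros(5)
        counts = np.zeros(5)
        for k in range(20):
            state, _, _ = ls.advance(state, dpd_ff, integ,
                                     rng.advanced(500 + 50 * k), 50)
            w = state.wrapped()
            idx = np.clip(np.digitize(w.positions[:, 1], edges) - 1, 0, 4)
            np.add.at(sums, idx, w.momenta[:, 0] / w.masses)
            np.add.at(counts, idx, 1.0)
        mean_pec = sums / counts
        # ~1500 samples per bin, sigma ~ 1 => SE ~ 0.026 per bin
        np.testing.assert_allclose(mean_pec, 0.0, atol=0.12)
        centers = 0.5 * (edges[1:] + edges[:-1])
        lab = mean_pec + g * centers
        slope = np.polyfit(centers, lab, 1)[0]
        assert slope == pytest.approx(g, rel=0.15)


class TestMotherDaughter:
    def test_mother_snapshot_protocol(self, dpd_ff, dpd_box):
        params = ls.SimulationParams(n_equilibration_steps=100,
                                     mother_sampling_interval=20,
                                     n_daughters=8, daughter_length=10,
                                     use_mappings=True)
        state0 = ls.init_configuration(3.0, dpd_box, 1.0, seed=1)
        snaps = list(ls.run_mother(state0, dpd_ff, params,
                                   ls.RandomStreamSpec(2)))
        assert len(snaps) == 2  # 8 daughters / 4 mappings
        assert snaps[0].time == pytest.approx((100 + 20) * 0.01)
        # snapshots are deep copies
        snaps[0].positions[:] = 0.0
        assert not np.all(snaps[1].positions == 0.0)

    def test_invalid_sampling_interval(self):
        with pytest.raises(ValueError):
            ls.SimulationParams(mother_sampling_interval=0)

    def test_daughter_series_shape(self, dpd_ff, dpd_thermal_state):
        params = ls.SimulationParams(shear_rate=1e-2, daughter_length=420)
        series = ls.run_daughter(dpd_thermal_state, dpd_ff, params,
                                 ls.RandomStreamSpec(3))
        assert series.pyx.shape == (421,)
        assert series.time[0] == 0.0
        assert series.time[-1] == pytest.approx(4.2)

    def test_motionless_single_particle_has_zero_stress(self, wca_ff):
        box = ls.BoxSpec.cubic(10.0)
        state = ls.PhasePoint(np.array([[5.0, 5, 5]]), np.zeros((1, 3)),
                              np.ones(1), box)
        params = ls.SimulationParams(shear_rate=1e-3, daughter_length=50,
                                     timestep=1e-3)
        series = ls.run_daughter(state, wca_ff, params,
                                 ls.RandomStreamSpec(0))
        np.testing.assert_array_equal(series.pyx, 0.0)
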