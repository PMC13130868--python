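"""Mappings, direct averaging and the TTCF estimator identities."""

import numpy as np
import pytest

import lowshear as ls
from lowshear.ttcf import TransientTimeCorrelation


def _brute_ttcf(values, dt, g, vol, kbt, corrected, impose_zero):
    """Scalar-loop reference: explicit covariance and trapezoid sums."""
    n, m = values.shape
    out = np.empty(m)
    m0 = sum(values[i, 0] for i in range(n)) / n
    integrand = []
    for s in range(m):
        c = sum(values[i, 0] * values[i, s] for i in range(n)) / n
        if corrected:
            ms = sum(values[i, s] for i in range(n)) / n
            c -= m0 * ms
        integrand.append(c)
    base = 0.0 if impose_zero else m0
    integral = 0.0
    out[0] = base
    for s in range(1, m):
        integral += 0.5 * dt * (integrand[s - 1] + integrand[s])
        out[s] = base - g * vol / kbt * integral
    return out


def _small_ensemble():
    values = np.array([[0.0, 1.0, 2.0, 1.5],
                       [1.0, 0.0, 1.0, -0.5],
                       [2.0, 2.0, 0.0, 1.0]])
    t = 0.1 * np.arange(4)
    return ls.StressSeriesEnsemble(values, t, shear_rate=0.5, volume=10.0,
                                   kbt=2.0)


class TestApplyMapping:
    def test_momentum_reversal(self, dpd_thermal_state):
        mapped = ls.apply_mapping(dpd_thermal_state, 1)
        np.testing.assert_array_equal(mapped.momenta,
                                      -dpd_thermal_state.momenta)
        np.testing.assert_array_equal(mapped.positions,
                                      dpd_thermal_state.positions)

    def test_identity_map(self, dpd_thermal_state):
        mapped = ls.apply_mapping(dpd_thermal_state, 0)
        np.testing.assert_array_equal(mapped.positions,
                                      dpd_thermal_state.positions)
        np.testing.assert_array_equal(mapped.momenta,
                                      dpd_thermal_state.momenta)

    def test_invalid_id(self, dpd_thermal_state):
        with pytest.raises(ValueError):
            ls.apply_mapping(dpd_thermal_state, 4)

    def test_involutions(self, dpd_thermal_state):
        for m in range(4):
            twice = ls.apply_mapping(ls.apply_mapping(dpd_thermal_state, m),
                                     m)
            np.testing.assert_array_equal(twice.positions,
                                          dpd_thermal_state.positions)
            np.testing.assert_array_equal(twice.momenta,
                                          dpd_thermal_state.momenta)

    def test_initial_stress_relations_wca(self, wca_ff, wca_thermal_state):
        """P_yx(0) = P'_yx(0) = -P''_yx(0) = -P'''_yx(0) for WCA."""
        vals = []
        for m in range(4):
            img = ls.apply_mapping(wca_thermal_state, m)
            res = ls.compute_all_forces(img, wca_ff, 1e-2,
                                        ls.RandomStreamSpec(0), 1e-3)
            vals.append(ls.pressure_tensor(img, res).p_yx)
        assert vals[1] == vals[0]
        assert vals[2] == -vals[0]
        assert vals[3] == -vals[0]
        assert abs(sum(vals)) <= 1e-14


class TestDirectAverage:
    def test_mean_of_two_rows(self):
        ens = ls.StressSeriesEnsemble(np.array([[0.0, 2.0], [2.0, 0.0]]),
                                      np.array([0.0, 0.1]), 0.0, 1.0, 1.0)
        est = ls.dav(ens)
        np.testing.assert_allclose(est.mean_response, [1.0, 1.0])

    def test_identical_rows_have_zero_se(self):
        ens = ls.StressSeriesEnsemble(np.tile([0.5, -0.5, 1.0], (4, 1)),
                                      np.array([0.0, 0.1, 0.2]), 0.0, 1.0,
                                      1.0)
        est = ls.dav(ens)
        np.testing.assert_array_equal(est.se, 0.0)
        np.testing.assert_array_equal(est.ci95_low, est.mean_response)

    def test_requires_two_rows(self):
        with pytest.raises(ValueError):
            ls.DirectAverage().fit(np.ones((1, 5)))

    def test_ci_brackets_mean(self):
        rng = np.random.default_rng(0)
        est = ls.DirectAverage().fit(rng.normal(size=(50, 7)))
        assert np.all(est.ci95_low_ <= est.mean_response_)
        assert np.all(est.mean_response_ <= est.ci95_high_)


class TestTtcfEstimator:
    def test_zero_shear_is_flat(self):
        ens = _small_ensemble()
        ens.shear_rate = 0.0
        est = ls.ttcf(ens, corrected=True)
        np.testing.assert_allclose(est.mean_response,
                                   ens.values[:, 0].mean())

    @pytest.mark.parametrize("corrected", [False, True])
    @pytest.mark.parametrize("impose_zero", [False, True])
    def test_against_scalar_loop_oracle(self, corrected, impose_zero):
        ens = _small_ensemble()
        est = ls.ttcf(ens, corrected=corrected,
                      impose_zero_initial=impose_zero)
        ref = _brute_ttcf(ens.values, 0.1, 0.5, 10.0, 2.0, corrected,
                          impose_zero)
        np.testing.assert_allclose(est.mean_response, ref, atol=1e-13)

    def test_frozen_example(self):
        # corrected, empirical initial value; precomputed with _brute_ttcf
        ens = _small_ensemble()
        est = ls.ttcf(ens, corrected=True, impose_zero_initial=False)
        np.testing.assert_allclose(
            est.mean_response,
            [1.0, 0.875, 0.9166666666666667, 1.0208333333333333],
            atol=1e-10)

    def test_correction_difference_identity(self):
        """uncorrected - corrected = -(gV/kBT)*<P0>*trapz(<Ps>), exactly."""
        rng = np.random.default_rng(3)
        values = rng.normal(0.2, 1.0, size=(40, 30))
        t = 0.05 * np.arange(30)
        ens = ls.StressSeriesEnsemble(values, t, 0.3, 7.0, 1.5)
        unc = ls.ttcf(ens, corrected=False).mean_response
        cor = ls.ttcf(ens, corrected=True).mean_response
        from scipy.integrate import cumulative_trapezoid
        pref = 0.3 * 7.0 / 1.5
        expected = -pref * values[:, 0].mean() * cumulative_trapezoid(
            values.mean(axis=0), t, initial=0.0)
        np.testing.assert_allclose(unc - cor, expected, atol=1e-13)

    def test_trajectorywise_linearity_identity(self):
        """Integral inside or outside the ensemble mean: same response."""
        rng = np.random.default_rng(4)
        values = rng.normal(0.0, 1.0, size=(25, 40))
        ens = ls.StressSeriesEnsemble(values, 0.01 * np.arange(40), 0.01,
                                      125.0, 1.0)
        for corrected in (False, True):
            a = ls.ttcf(ens, corrected=corrected).mean_response
            b = ls.ttcf_trajectorywise(ens, corrected=corrected)
            np.testing.assert_allclose(a, b, atol=1e-12)

    def test_impose_zero_keeps_empirical_covariance(self):
        ens = _small_ensemble()
        a = ls.ttcf(ens, corrected=True, impose_zero_initial=True)
        b = ls.ttcf(ens, corrected=True, impose_zero_initial=False)
        m0 = ens.values[:, 0].mean()
        np.testing.assert_allclose(b.mean_response - a.mean_response, m0,
                                   atol=1e-14)

    def test_requires_two_rows(self):
        with pytest.raises(ValueError):
            TransientTimeCorrelation(dt=0.1).fit(np.ones((1, 5)))

    def test_sklearn_protocol(self):
        est = TransientTimeCorrelation(shear_rate=0.1, volume=5.0)
        params = est.get_params()
        assert params["shear_rate"] == 0.1
        est.set_params(shear_rate=0.2)
        assert est.shear_rate == 0.2


class TestEnsembleValidation:
    def test_grid_mismatch(self):
        with pytest.raises(ValueError):
            ls.StressSeriesEnsemble(np.ones((2, 3)), np.array([0.0, 0.1]),
                                    0.0, 1.0, 1.0)

    def test_grid_must_start_at_zero(self):
        with pytest.raises(ValueError):
            ls.StressSeriesEnsemble(np.ones((2, 3)),
                                    np.array([0.1, 0.2, 0.3]), 0.0, 1.0, 1.0)

    def test_quadruplet_grouping(self):
        with pytest.raises(ValueError):
            ls.StressSeriesEnsemble(np.ones((4, 2)), np.array([0.0, 0.1]),
                                    0.0, 1.0, 1.0,
                                    mapped_groups=np.arange(4).reshape(2, 2))


class TestRunExperiment:
    def test_shapes_and_determinism(self, dpd_ff, dpd_box):
        params = ls.SimulationParams(shear_rate=1e-2, timestep=0.01,
                                     n_equilibration_steps=100,
                                     mother_sampling_interval=20,
                                     n_daughters=8, daughter_length=10)
        a = ls.run_ttcf_experiment(params, dpd_ff, 5, density=3.0,
                                   box=dpd_box)
        b = ls.run_ttcf_experiment(params, dpd_ff, 5, density=3.0,
                                   box=dpd_box)
        assert a.ensemble.values.shape == (8, 11)
        np.testing.assert_array_equal(a.ensemble.values, b.ensemble.values)
        assert set(a.estimates) == {"DAV", "TTCF"}
        assert a.estimates["TTCF"].method == "TTCF_UNMAPPED"

    def test_mapped_pipeline(self, wca_ff):
        n, rho = 108, 0.8442
        box = ls.BoxSpec.cubic((n / rho) ** (1 / 3))
        thermo = ls.ThermostatState(
            ls.default_nose_hoover_q(n, 1.0, 0.722, 2.5e-3))
        params = ls.SimulationParams(timestep=2.5e-3, shear_rate=1e-4,
                                     n_equilibration_steps=200,
                                     mother_sampling_interval=50,
                                     n_daughters=8, daughter_length=10,
                                     use_mappings=True, thermostat=thermo)
        res = ls.run_ttcf_experiment(params, wca_ff, 6, density=rho, box=box,
                                     lattice="fcc")
        assert res.ensemble.values.shape == (8, 11)
        assert res.ensemble.mapped_groups.shape == (2, 4)
        assert res.estimates["TTCF"].method == "TTCF_MAPPED"
        # quadruplet initial stresses cancel pairwise
        v0 = res.ensemble.values[:, 0].reshape(2, 4)
        np.testing.assert_allclose(v0.mean(axis=1), 0.0, atol=1e-14)

    def test_partial_quadruplets_rejected(self):
        with pytest.raises(ValueError):
            ls.SimulationParams(n_daughters=6, use_mappings=True)
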