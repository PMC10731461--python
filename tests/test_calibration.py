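"""Objective, constrained fitting, bootstrap CIs and quality measures."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from by2sim.calibration import (
    SIMULATION_PENALTY,
    ConfigurationError,
    FitProblem,
    TimeSeriesDataset,
    UndefinedMetricError,
    bootstrap_ci,
    error_matrix,
    fit,
    grand_mean,
    mae,
    mae_subset,
    nmae,
    objective,
    predict_responses,
)
from by2sim.kinetics import KineticParametersInitial, ProcessState
from by2sim.process_sim import ExperimentDesign
from by2sim.synthetic_data import NoiseSpec, make_study, zero_noise

from conftest import FAST

FREE_RATES = ("mu_m", "mu_S", "mu_A", "mu_N")


def constant_params():
    """All rates zero: the model predicts constant initial concentrations."""
    return KineticParametersInitial(K_S=1.0, K_IS=1.0, K_A=1.0, K_IA=1.0,
                                    K_N=1.0, K_IN=1.0)


def toy_dataset(values=None, times=(0.0, 48.0)):
    init = ProcessState(V=1.0, Xa=2.0, S=10.0, A=0.4, N=2.4, P=0.2)
    design = ExperimentDesign(label="toy", variant="initial", initial=init,
                              duration=100.0)
    t = np.asarray(times, dtype=float)
    if values is None:
        values = {"X": np.full_like(t, 2.0), "S": np.full_like(t, 10.0)}
    return TimeSeriesDataset(label="toy", design=design,
                             times={r: t.copy() for r in values},
                             values={r: np.asarray(v, dtype=float)
                                     for r, v in values.items()})


@pytest.fixture(scope="module")
def study(ref_initial):
    """Three noiseless synthetic runs from the reference initial model."""
    return make_study([1, 2, 3], ref_initial, noise=zero_noise(), seed=1,
                      solver=FAST)


class TestObjective:
    def test_perfect_fit_is_zero(self):
        ds = toy_dataset()
        prob = FitProblem([ds], constant_params(), responses=("X", "S"),
                          solver=FAST)
        assert objective(constant_params(), prob) == pytest.approx(0.0, abs=1e-12)

    def test_single_point_relative_residual(self):
        # g = 2 (constant model), y = 2/0.9 -> (1 - 0.9)^2 = 0.01
        ds = toy_dataset(values={"X": [2.0 / 0.9]}, times=[0.0])
        prob = FitProblem([ds], constant_params(), responses=("X",), solver=FAST)
        assert objective(constant_params(), prob) == pytest.approx(0.01, rel=1e-10)

    def test_hand_computed_toy_table(self):
        # constant predictions g_X = 2, g_S = 10 against a 2x2 toy table:
        # Q = (1-2/2)^2 + (1-2/4)^2 + (1-10/10)^2 + (1-10/5)^2 = 0.25 + 1.0
        ds = toy_dataset(values={"X": [2.0, 4.0], "S": [10.0, 5.0]})
        prob = FitProblem([ds], constant_params(), responses=("X", "S"),
                          solver=FAST)
        assert objective(constant_params(), prob) == pytest.approx(1.25, rel=1e-10)

    def test_permutation_invariance_across_datasets(self, ref_initial, study):
        perturbed = ref_initial.replace(mu_m=8.5)
        q1 = objective(perturbed, FitProblem(list(study), ref_initial, solver=FAST))
        q2 = objective(perturbed, FitProblem(list(study)[::-1], ref_initial,
                                             solver=FAST))
        assert q1 == pytest.approx(q2, rel=1e-12)

    def test_doubled_weight_doubles_contribution(self):
        ds = toy_dataset(values={"X": [2.0, 4.0], "S": [10.0, 5.0]})
        base = dict(datasets=[ds], base_params=constant_params(),
                    responses=("X", "S"), solver=FAST)
        q_x1 = objective(constant_params(),
                         FitProblem(**base, weights={"S": 0.0}))
        q_w2 = objective(constant_params(),
                         FitProblem(**base, weights={"X": 2.0, "S": 0.0}))
        assert q_w2 == pytest.approx(2.0 * q_x1, rel=1e-12)

    def test_low_measurements_guarded(self):
        # the relative residual is undefined at y ~ 0: such rows are dropped
        ds = toy_dataset(values={"S": [10.0, 0.0]})
        prob = FitProblem([ds], constant_params(), responses=("S",), solver=FAST)
        assert np.isfinite(objective(constant_params(), prob))

    def test_unsimulable_parameters_get_penalty(self):
        ds = toy_dataset()
        prob = FitProblem([ds], constant_params(), responses=("X",), solver=FAST)
        bad = constant_params().replace(mu_m=1e9)  # blows up the integrator
        assert objective(bad, prob) == SIMULATION_PENALTY


class TestFit:
    def test_collapsed_bounds_return_that_point(self, study, ref_initial):
        bounds = {n: (getattr(ref_initial, n),) * 2
                  for n in KineticParametersInitial.NAMES}
        prob = FitProblem(list(study), ref_initial, free=("mu_m", "mu_S"),
                          bounds=bounds, solver=FAST)
        res = fit(prob, n_starts=2, seed=0, maxiter=20)
        assert res.params.mu_m == ref_initial.mu_m
        assert res.params.mu_S == ref_initial.mu_S

    def test_noiseless_recovery_of_rate_parameters(self, study, ref_initial):
        start = ref_initial.replace(mu_m=8.0, mu_S=0.3)
        prob = FitProblem(list(study), start, free=FREE_RATES, solver=FAST)
        res = fit(prob, n_starts=2, seed=0, maxiter=120)
        assert res.q < 1e-6
        for name in FREE_RATES:
            assert getattr(res.params, name) == pytest.approx(
                getattr(ref_initial, name), rel=1e-2)

    def test_one_dimensional_fit_matches_scalar_scan(self, study, ref_initial):
        # independent oracle: bounded golden-section/Brent scan of Q(mu_S)
        start = ref_initial.replace(mu_S=0.4)
        prob = FitProblem(list(study), start, free=("mu_S",), solver=FAST)
        res = fit(prob, n_starts=1, seed=0, maxiter=80)
        scan = minimize_scalar(lambda v: objective(np.array([v]), prob),
                               bounds=(0.0, 1.0), method="bounded",
                               options={"xatol": 1e-8})
        assert res.params.mu_S == pytest.approx(scan.x, abs=1e-4)

    def test_objective_never_worse_than_start(self, study, ref_initial):
        start = ref_initial.replace(mu_m=5.0)
        prob = FitProblem(list(study), start, free=("mu_m",), solver=FAST)
        res = fit(prob, n_starts=1, seed=0, maxiter=3)  # starved on purpose
        assert res.q <= objective(start, prob) + 1e-12

    def test_inhibition_constraint_respected(self, study, ref_initial):
        prob = FitProblem(list(study), ref_initial, free=("K_S", "K_IS"),
                          solver=FAST)
        res = fit(prob, n_starts=2, seed=3, maxiter=40)
        assert res.params.K_IS >= res.params.K_S - 1e-6

    def test_unknown_free_name_rejected(self, study, ref_initial):
        with pytest.raises(ConfigurationError):
            FitProblem(list(study), ref_initial, free=("not_a_param",))


class TestErrorMatrix:
    def test_zero_uncertainty_gives_zeros(self):
        ds = toy_dataset()
        ds.noise = NoiseSpec(u_prop={})
        sig = error_matrix([ds])["toy"]
        assert all(np.all(v == 0.0) for v in sig.values())

    def test_constant_plus_proportional(self):
        ds = toy_dataset(values={"S": [10.0]}, times=[0.0])
        ds.noise = NoiseSpec(u0={"S": 0.1}, u_prop={"S": 0.06})
        assert error_matrix([ds])["toy"]["S"][0] == pytest.approx(0.7)

    def test_default_percentages(self):
        ds = toy_dataset(values={"X": [2.0, 4.0], "S": [10.0, 5.0]})
        ds.noise = NoiseSpec()  # 3 % on dry mass, 6 % per nutrient
        sig = error_matrix([ds])["toy"]
        assert np.allclose(sig["X"], [0.06, 0.12])
        assert np.allclose(sig["S"], [0.6, 0.3])

    def test_missing_noise_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            error_matrix([toy_dataset()])


class TestBootstrap:
    def test_zero_noise_gives_zero_width(self, study, ref_initial):
        prob = FitProblem(list(study), ref_initial, free=("mu_m", "mu_S"),
                          solver=FAST)
        res = fit(prob, n_starts=1, seed=0, maxiter=40)
        table = bootstrap_ci(res, n_boot=3, seed=0)
        assert np.allclose(table["ci_high"] - table["ci_low"], 0.0, atol=1e-10)

    def test_deterministic_under_seed(self, ref_initial):
        ds = make_study([1], ref_initial, seed=4, solver=FAST)
        prob = FitProblem(ds, ref_initial, free=("mu_S",), solver=FAST)
        res = fit(prob, n_starts=1, seed=0, maxiter=40)
        t1 = bootstrap_ci(res, n_boot=2, seed=11, refit_maxiter=20)
        t2 = bootstrap_ci(res, n_boot=2, seed=11, refit_maxiter=20)
        pd.testing.assert_frame_equal(t1, t2)

    def test_matches_linearized_error_propagation(self, ref_initial):
        # near-linear reduction: growth off, nearly saturated uptake of one
        # nutrient (K_S small but positive so the rate stays smooth at S = 0);
        # the closed-form (sandwich) CI from numerical sensitivities is the
        # independent oracle for the bootstrap percentile interval
        p_true = ref_initial.replace(mu_m=0.0, kd=0.0, K_S=0.5, K_IS=1e6,
                                     mu_A=0.0, mu_N=0.0, mu_P=0.0, mu_S=0.12)
        init = ProcessState(V=1.0, Xa=2.0, S=25.0, A=0.4, N=2.4, P=0.2)
        design = ExperimentDesign(
            label="lin", variant="initial", initial=init, duration=72.0,
            sampling_times=np.arange(0.0, 73.0, 12.0))
        noise = NoiseSpec(u0={"S": 0.4}, u_prop={})
        from by2sim.synthetic_data import generate
        ds = generate(design, p_true, noise=noise, rng=7, solver=FAST)
        prob = FitProblem([ds], p_true, free=("mu_S",), responses=("S",),
                          solver=FAST)
        res = fit(prob, n_starts=1, seed=0, maxiter=60)
        table = bootstrap_ci(res, n_boot=250, seed=5, refit_maxiter=30)

        # oracle: linearize g(mu_S) at the optimum, propagate sigma = u0
        mu_hat = res.params.mu_S
        h = 1e-5
        g0 = predict_responses(res.params, design, {"S": ds.times["S"]}, FAST)["S"]
        g1 = predict_responses(res.params.replace(mu_S=mu_hat + h), design,
                               {"S": ds.times["S"]}, FAST)["S"]
        sens = (g1 - g0) / h
        y = ds.values["S"]
        J = sens / y  # gradient of the relative residual r = 1 - g/y
        var = np.sum((J * 0.4 / y) ** 2) / np.sum(J ** 2) ** 2
        half = 1.645 * np.sqrt(var)
        width = float(table.loc["mu_S", "ci_high"] - table.loc["mu_S", "ci_low"])
        assert width == pytest.approx(2 * half, rel=0.25)


class TestQualityMeasures:
    def test_perfect_prediction_zero_mae(self):
        ds = toy_dataset()
        assert mae(constant_params(), ds, "X", FAST) == 0.0

    def test_hand_computed_mae(self):
        ds = toy_dataset(values={"X": [1.0, 3.0]})  # predictions are 2, 2
        assert mae(constant_params(), ds, "X", FAST) == pytest.approx(1.0)

    def test_nmae_normalizes_by_grand_mean(self):
        ds = toy_dataset(values={"X": [1.0, 3.0]})
        assert grand_mean([ds], "X") == pytest.approx(2.0)
        assert nmae(constant_params(), ds, "X", [ds], FAST) == pytest.approx(0.5)

    def test_pooled_subset_mae_hand_summed(self):
        # two experiments with 2 + 1 observations: pooled mean of |y - g|
        ds1 = toy_dataset(values={"X": [1.0, 3.0]})
        ds2 = toy_dataset(values={"X": [2.5]}, times=[0.0])
        val = mae_subset(constant_params(), [ds1, ds2], "X", FAST)
        assert val == pytest.approx((1.0 + 1.0 + 0.5) / 3.0)

    def test_empty_response_is_undefined(self):
        ds = toy_dataset()
        with pytest.raises(UndefinedMetricError):
            mae(constant_params(), ds, "G", FAST)
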