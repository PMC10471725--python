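"""The continuation core: DPsi solve, predictor, corrector, paths."""

import numpy as np
import pytest

from mlecont import (
    CalibrationData,
    MLEContinuation,
    ObjectiveSpec,
    ParameterVector,
    SingularHessianError,
    build_continuation_state,
    compute_dpsi,
    continuation_path,
    correct_mle,
    objective,
    predict_mle,
)
from mlecont.models import linear_dpsi, linear_mle, linear_model


class TestComputeDpsi:
    def test_scalar_mean_model(self):
        # y_i = theta for d points, sigma = 1: H = 2d, M = -2 ones;
        # the MLE is the sample mean, so each data point carries 1/d
        d = 4
        H = np.array([[2.0 * d]])
        M = -2.0 * np.ones((1, d))
        np.testing.assert_allclose(compute_dpsi(H, M), np.full((1, d), 1.0 / d))

    def test_zero_mixed_partial_gives_zero(self):
        np.testing.assert_allclose(
            compute_dpsi(np.eye(2), np.zeros((2, 3))), np.zeros((2, 3))
        )

    def test_linear_model_matches_normal_equations(self, linear_problem):
        X, phi, model, theta0, data = linear_problem
        fit = correct_mle(model, data, theta0)
        state = build_continuation_state(model, fit.theta, data)
        np.testing.assert_allclose(state.dpsi, linear_dpsi(X), rtol=1e-5, atol=1e-8)

    def test_singular_hessian_names_null_direction(self):
        H = np.array([[1.0, 1.0], [1.0, 1.0 + 1e-15]])
        with pytest.raises(SingularHessianError, match="unidentifiability"):
            compute_dpsi(H, np.zeros((2, 1)), parameter_names=("a", "b"))

    def test_residual_equation_holds(self, linear_problem):
        X, phi, model, theta0, data = linear_problem
        fit = correct_mle(model, data, theta0)
        state = build_continuation_state(model, fit.theta, data)
        residual = state.hessian @ state.dpsi + state.mixed_partial
        assert np.abs(residual).max() < 1e-6 * np.abs(state.hessian).max()


class TestPredict:
    def test_zero_perturbation_returns_theta_star(self, linear_problem):
        X, phi, model, theta0, data = linear_problem
        fit = correct_mle(model, data, theta0)
        state = build_continuation_state(model, fit.theta, data)
        pred = predict_mle(state, np.zeros(data.d))
        np.testing.assert_allclose(pred.values, fit.theta.values)

    def test_scalar_mean_shift(self):
        # mean of (1, 2, 3) is 2; raising the first point by 0.3 moves the
        # mean by 0.1
        X = np.ones((3, 1))
        model, theta0 = linear_model(X)
        data = CalibrationData(np.arange(3), [1.0, 2.0, 3.0])
        fit = correct_mle(model, data, theta0)
        state = build_continuation_state(model, fit.theta, data)
        pred = predict_mle(state, np.array([0.3, 0.0, 0.0]))
        assert pred.values[0] == pytest.approx(2.1, rel=1e-6)

    def test_linear_prediction_equals_exact_refit(self, linear_problem):
        X, phi, model, theta0, data = linear_problem
        fit = correct_mle(model, data, theta0)
        state = build_continuation_state(model, fit.theta, data)
        rng = np.random.default_rng(3)
        for _ in range(5):
            dphi = rng.normal(size=6)
            pred = predict_mle(state, dphi)
            np.testing.assert_allclose(
                pred.values, linear_mle(X, phi + dphi), rtol=1e-5, atol=1e-7
            )

    def test_out_of_bounds_prediction_clips_with_warning(self):
        X = np.ones((2, 1))
        model, _ = linear_model(X)
        theta0 = ParameterVector([0.5], ["theta_0"], [0.0], [1.0])
        data = CalibrationData(np.arange(2), [0.5, 0.5])
        fit = correct_mle(model, data, theta0)
        state = build_continuation_state(model, fit.theta, data)
        with pytest.warns(UserWarning, match="clipped"):
            pred = predict_mle(state, np.array([10.0, 10.0]))
        assert pred.values[0] == 1.0


class TestCorrect:
    def test_start_at_minimum_stays(self, linear_problem):
        X, phi, model, theta0, data = linear_problem
        exact = linear_mle(X, phi)
        result = correct_mle(model, data, theta0.with_values(exact))
        np.testing.assert_allclose(result.theta.values, exact, rtol=1e-7, atol=1e-9)

    def test_objective_never_exceeds_start(self, linear_problem):
        X, phi, model, theta0, data = linear_problem
        start_obj = objective(model, theta0, data)
        result = correct_mle(model, data, theta0)
        assert result.objective_value <= start_obj + 1e-12
        assert result.converged

    def test_reaches_normal_equations_solution(self, linear_problem):
        X, phi, model, theta0, data = linear_problem
        result = correct_mle(model, data, theta0)
        np.testing.assert_allclose(
            result.theta.values, linear_mle(X, phi), rtol=1e-6, atol=1e-8
        )


class TestContinuationPath:
    def test_identical_datasets_give_identical_states(self, linear_problem):
        X, phi, model, theta0, data = linear_problem
        fit = correct_mle(model, data, theta0)
        path = continuation_path(model, fit.theta, [data, data, data])
        for step in path[1:]:
            np.testing.assert_allclose(
                step.state.theta_star.values, path[0].state.theta_star.values,
                rtol=1e-7, atol=1e-9,
            )

    def test_linear_path_tracks_exact_mle_each_step(self, linear_problem):
        X, phi, model, theta0, data = linear_problem
        rng = np.random.default_rng(5)
        datasets = [data] + [
            data.with_values(phi + rng.normal(size=6)) for _ in range(3)
        ]
        fit = correct_mle(model, data, theta0)
        path = continuation_path(model, fit.theta, datasets, mode="predict_only")
        for step, ds in zip(path[1:], datasets[1:]):
            np.testing.assert_allclose(
                step.state.theta_star.values, linear_mle(X, ds.values),
                rtol=1e-4, atol=1e-6,
            )

    def test_rejects_mismatched_designs(self, linear_problem):
        X, phi, model, theta0, data = linear_problem
        other = CalibrationData(np.arange(6) + 0.5, phi)
        fit = correct_mle(model, data, theta0)
        with pytest.raises(ValueError, match="share times"):
            continuation_path(model, fit.theta, [data, other])

    def test_cumulative_counts_increase(self, linear_problem):
        X, phi, model, theta0, data = linear_problem
        fit = correct_mle(model, data, theta0)
        path = continuation_path(
            model, fit.theta, [data, data.with_values(phi + 0.1)]
        )
        c0 = path[0].cumulative_counts["model_simulations"]
        c1 = path[1].cumulative_counts["model_simulations"]
        assert c1 > c0 > 0


class TestEstimator:
    def test_fit_predict_roundtrip(self, linear_problem):
        X, phi, model, theta0, data = linear_problem
        est = MLEContinuation(model=model).fit(data, theta0)
        assert est.dpsi_.shape == (3, 6)
        dphi = np.full(6, 0.2)
        pred = est.predict(data.with_values(phi + dphi))
        np.testing.assert_allclose(pred, linear_mle(X, phi + dphi), rtol=1e-5)

    def test_sklearn_param_interface(self, linear_problem):
        X, phi, model, theta0, data = linear_problem
        est = MLEContinuation(model=model, relative_step=2e-4)
        params = est.get_params()
        assert params["relative_step"] == 2e-4
        est.set_params(cond_threshold=1e8)
        assert est.cond_threshold == 1e8

    def test_unfitted_predict_raises(self, linear_problem):
        X, phi, model, theta0, data = linear_problem
        with pytest.raises(RuntimeError, match="not fitted"):
            MLEContinuation(model=model).predict(data)
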