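"""Experimental-design quantities built on the data->parameter Jacobian."""

import numpy as np
import pytest

from mlecont import (
    CalibrationData,
    append_simulated_measurement,
    bic,
    build_continuation_state,
    compare_minima_robustness,
    correct_mle,
    data_point_sensitivity,
    dpsi_norm1,
    most_informative_point,
    objective,
    rank_candidate_measurements,
    sensitivity_report,
)
from mlecont.models import linear_mle, linear_model


class TestPointSensitivity:
    @pytest.mark.parametrize(
        "dpsi, k, expected",
        [
            ([[1.0, 0.0], [0.0, 2.0]], 0, 1.0),
            ([[1.0, 0.0], [0.0, 2.0]], 1, 2.0),
            ([[1.0, -2.0], [3.0, 4.0]], 1, 6.0),
            ([[0.0, 1.0], [0.0, 1.0]], 0, 0.0),
        ],
    )
    def test_absolute_column_sums(self, dpsi, k, expected):
        assert data_point_sensitivity(np.array(dpsi), k) == expected

    def test_index_out_of_range(self):
        with pytest.raises(IndexError):
            data_point_sensitivity(np.eye(2), 2)

    def test_most_informative_and_norm(self):
        dpsi = np.array([[1.0, 0.0], [0.0, 2.0]])
        assert most_informative_point(dpsi) == (1, 2.0)
        assert dpsi_norm1(dpsi) == 2.0

    def test_tie_breaks_to_earliest_point(self):
        dpsi = np.array([[1.0, 1.0], [2.0, 2.0]])
        assert most_informative_point(dpsi) == (0, 3.0)

    def test_never_selects_zero_column(self):
        dpsi = np.array([[0.0, 0.5]])
        assert most_informative_point(dpsi)[0] == 1


class TestSensitivityReport:
    def test_invariants_and_permutation_equivariance(self, linear_problem):
        X, phi, model, theta0, data = linear_problem
        fit = correct_mle(model, data, theta0)
        state = build_continuation_state(model, fit.theta, data)
        report = sensitivity_report(state)
        np.testing.assert_allclose(
            report.per_point_sensitivity, np.abs(state.dpsi).sum(axis=0)
        )
        assert report.dpsi_norm == report.per_point_sensitivity.max()
        assert (
            report.per_point_sensitivity[report.most_informative_index]
            == report.dpsi_norm
        )
        frame = report.to_frame()
        assert list(frame.index) == list(fit.theta.names) + ["column-sum"]


class TestBIC:
    def test_equal_fits_equal_bic(self):
        assert bic(1.5, 4, 8) == bic(1.5, 4, 8)

    def test_delta_depends_only_on_delta_objective(self):
        assert bic(2.0, 4, 8) - bic(1.0, 4, 8) == pytest.approx(2.0)

    def test_monotone_in_objective(self):
        assert bic(3.0, 4, 8) > bic(1.0, 4, 8)

    def test_rejects_empty_data(self):
        with pytest.raises(ValueError):
            bic(1.0, 2, 0)


class TestAppendedMeasurements:
    def test_exact_point_leaves_objective_unchanged(self, phenotype_fit):
        model, theta_true, data, spec, fit, state = phenotype_fit
        g0 = objective(model, fit.theta, data, spec)
        augmented, _ = append_simulated_measurement(
            model, fit.theta, data, 3.1, "treated", 0.0
        )
        g1 = objective(model, fit.theta, augmented, spec)
        assert abs(g1 - g0) < 1e-8

    def test_append_increments_row_count(self, phenotype_fit):
        model, theta_true, data, spec, fit, state = phenotype_fit
        augmented, idx = append_simulated_measurement(
            model, fit.theta, data, 5.0, "treated", 0.1
        )
        assert augmented.d == data.d + 1
        assert augmented.conditions[idx] == "treated"


class TestCandidateRanking:
    def test_tornado_antisymmetry_and_direction(self, phenotype_fit):
        model, theta_true, data, spec, fit, state = phenotype_fit
        probe, probe_idx = append_simulated_measurement(
            model, fit.theta, data, 3.1, "treated"
        )
        delta = 0.3 * float(probe.values[probe_idx])
        table = rank_candidate_measurements(
            model, state, [3.1, 5.0], "treated", delta,
            target_parameter="d_A_max", spec=spec,
        )
        for time in (3.1, 5.0):
            rows = table[table["time"] == time].sort_values("delta_phi")
            lo, hi = rows["percent_d_A_max"].to_numpy()
            # first-order antisymmetry around the exact simulated point
            assert lo * hi < 0
            assert rows.iloc[0]["delta_phi"] < 0 < rows.iloc[1]["delta_phi"]
        # at the population nadir the measurement is kill-dominated:
        # a lowered count raises the fitted kill rate and vice versa
        nadir = table[table["time"] == 5.0].sort_values("delta_phi")
        lo, hi = nadir["percent_d_A_max"].to_numpy()
        assert lo > 0 > hi

    def test_ranks_are_a_permutation(self, phenotype_fit):
        model, theta_true, data, spec, fit, state = phenotype_fit
        table = rank_candidate_measurements(
            model, state, [3.2, 6.5], "treated", 10.0, spec=spec
        )
        assert sorted(table["rank"]) == [1, 2, 3, 4]


class TestCompareMinima:
    def test_identical_candidates_have_ratio_one(self, linear_problem):
        X, phi, model, theta0, data = linear_problem
        mle = theta0.with_values(linear_mle(X, phi))
        table = compare_minima_robustness(model, data, [mle, mle])
        np.testing.assert_allclose(table["ratio_to_first"], [1.0, 1.0], rtol=1e-9)

    def test_linear_norm_is_data_independent(self, linear_problem):
        X, phi, model, theta0, data = linear_problem
        other = data.with_values(phi + 1.3)
        t1 = compare_minima_robustness(
            model, data, [theta0.with_values(linear_mle(X, phi))]
        )
        t2 = compare_minima_robustness(
            model, other, [theta0.with_values(linear_mle(X, phi + 1.3))]
        )
        assert t1["norm1"].iloc[0] == pytest.approx(t2["norm1"].iloc[0], rel=1e-6)

    def test_warns_for_non_stationary_candidate(self, linear_problem):
        X, phi, model, theta0, data = linear_problem
        bad = theta0.with_values(linear_mle(X, phi) + 5.0)
        with pytest.warns(UserWarning, match="stationary"):
            compare_minima_robustness(model, data, [bad])

    def test_order_invariance(self, linear_problem):
        X, phi, model, theta0, data = linear_problem
        mle = theta0.with_values(linear_mle(X, phi))
        near = theta0.with_values(linear_mle(X, phi) * (1 + 1e-9))
        a = compare_minima_robustness(model, data, [mle, near])
        b = compare_minima_robustness(model, data, [near, mle])
        np.testing.assert_allclose(
            sorted(a["norm1"]), sorted(b["norm1"]), rtol=1e-9
        )
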