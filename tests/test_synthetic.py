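"""Seeded data generators: determinism, noise calibration, constraints."""

import numpy as np
import pytest

from mlecont import (
    CalibrationData,
    PerturbationScheme,
    generate_model_baseline,
    generate_viral_baseline,
    perturb_absolute,
    perturb_log,
    perturb_norm_scaled,
)
from mlecont.models import linear_model
from mlecont.models.viral import REFERENCE_TIMES, viral_model


@pytest.fixture(scope="module")
def flat_baseline():
    """A cheap constant-observable baseline for noise-model statistics."""
    model, theta0 = linear_model(np.ones((2000, 1)))
    theta = theta0.with_values(np.array([5.0]))
    return model, theta


class TestBaselines:
    def test_zero_noise_reproduces_model_output(self):
        model, theta = viral_model()
        data = generate_viral_baseline(model, theta, REFERENCE_TIMES, sigma2=0.0)
        noisy = generate_viral_baseline(
            model, theta, REFERENCE_TIMES, sigma2=0.15, seed=1
        )
        assert not np.allclose(data.values, noisy.values)
        from mlecont import simulate_observables

        np.testing.assert_allclose(
            data.values, simulate_observables(model, theta, data)
        )

    def test_fixed_seed_is_bit_identical(self):
        model, theta = viral_model()
        a = generate_viral_baseline(model, theta, REFERENCE_TIMES, seed=9)
        b = generate_viral_baseline(model, theta, REFERENCE_TIMES, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_noise_variance_calibrated(self, flat_baseline):
        # 2000 draws of the additive Gaussian noise: sample variance
        # within 5% of the nominal 0.15
        model, theta = flat_baseline
        data = generate_model_baseline(
            model, theta, np.arange(2000), noise_sd=np.sqrt(0.15), seed=17
        )
        eps = data.values - 5.0
        assert np.var(eps) == pytest.approx(0.15, rel=0.05)


class TestAbsoluteScheme:
    def test_positive_step_shifts_every_point_up(self, flat_baseline):
        model, theta = flat_baseline
        base = CalibrationData(np.arange(8), np.zeros(8))
        pert = perturb_absolute(base, 0.1, seed=3)
        assert np.all(pert.values >= base.values)
        down = perturb_absolute(base, -0.1, seed=3)
        assert np.all(down.values <= base.values)

    def test_zero_step_is_identity(self):
        base = CalibrationData(np.arange(4), np.array([1.0, 2.0, 3.0, 4.0]))
        np.testing.assert_array_equal(
            perturb_absolute(base, 0.0, seed=3).values, base.values
        )

    def test_half_normal_mean_shift(self):
        # E|eps| = sqrt(2/pi) ~ 0.7979, so h = 0.1 shifts by ~0.0798
        base = CalibrationData(np.arange(10000), np.zeros(10000))
        pert = perturb_absolute(base, 0.1, seed=5)
        assert pert.values.mean() == pytest.approx(0.0798, rel=0.03)


class TestLogScheme:
    def test_zero_scale_is_identity(self):
        base = CalibrationData(np.arange(3), np.array([1.0, 2.0, 3.0]))
        np.testing.assert_array_equal(
            perturb_log(base, 0.0, seed=1).values, base.values
        )

    def test_positivity_preserved(self):
        base = CalibrationData(np.arange(50), np.full(50, 1e-3))
        for seed in range(5):
            assert np.all(perturb_log(base, 0.8, seed=seed).values > 0)

    def test_log_residual_sd(self):
        base = CalibrationData(np.arange(10000), np.ones(10000))
        pert = perturb_log(base, 0.8, seed=11)
        assert np.std(np.log(pert.values)) == pytest.approx(0.8, rel=0.03)

    def test_rejects_nonpositive_values(self):
        base = CalibrationData([0.0], [-1.0])
        with pytest.raises(ValueError):
            perturb_log(base, 0.8)


class TestNormScaledScheme:
    def test_achieves_target_norm_exactly(self):
        base = CalibrationData(np.arange(6), np.array([100.0, 210.0, 300, 410, 250, 380]))
        for j in (1, 5, 10):
            pert = perturb_norm_scaled(base, j, 0.07, seed=2)
            achieved = np.linalg.norm(
                np.log10(pert.values) - np.log10(base.values)
            )
            target = (0.05 + 0.07 * j) * np.linalg.norm(np.log10(base.values))
            assert achieved == pytest.approx(target, abs=1e-12 * max(1, target))

    def test_zero_target_is_identity(self):
        base = CalibrationData(np.arange(3), np.array([10.0, 20.0, 30.0]))
        pert = perturb_norm_scaled(base, 1, 0.07, seed=4, base_offset=-0.07)
        np.testing.assert_array_equal(pert.values, base.values)

    def test_ordering_constraints_hold_for_many_seeds(self):
        base = CalibrationData(
            np.array([0, 2, 4, 6, 4, 6]),
            np.array([100.0, 400.0, 1500.0, 4000.0, 420.0, 260.0]),
            None,
            ["c", "c", "c", "c", "t", "t"],
        )
        constraints = ((4, 2), (5, 3))
        for seed in range(25):
            pert = perturb_norm_scaled(base, 8, 0.07, seed=seed, constraints=constraints)
            assert pert.values[4] <= pert.values[2]
            assert pert.values[5] <= pert.values[3]

    def test_retry_budget_error(self):
        base = CalibrationData(np.arange(2), np.array([10.0, 10.0]))
        # impossible constraint pair: both orderings simultaneously
        with pytest.raises(RuntimeError, match="constraints"):
            perturb_norm_scaled(
                base, 10, 0.07, seed=0,
                constraints=((0, 1), (1, 0)), max_retries=20,
            )


class TestScheme:
    def test_dispatch_and_determinism(self):
        base = CalibrationData(np.arange(4), np.array([1.0, 2.0, 3.0, 4.0]))
        scheme = PerturbationScheme("log_additive", {"scale": 0.3}, seed=6)
        np.testing.assert_array_equal(
            scheme.apply(base).values, scheme.apply(base).values
        )

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            PerturbationScheme("jitter")
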