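"""Shared fixtures: closed-form linear problems and seeded model studies."""

import numpy as np
import pytest

from mlecont import (
    CalibrationData,
    ObjectiveSpec,
    correct_mle,
    build_continuation_state,
    generate_model_baseline,
)
from mlecont.models import linear_model
from mlecont.models.phenotype import (
    CONTROL_TIMES,
    TREATED_TIMES,
    phenotype_model,
)


@pytest.fixture()
def linear_problem():
    """Random full-rank 6x3 design with data, plus its ModelSpec wrapper."""
    rng = np.random.default_rng(42)
    X = rng.normal(size=(6, 3))
    phi = rng.normal(size=6)
    model, theta0 = linear_model(X)
    data = CalibrationData(np.arange(6), phi)
    return X, phi, model, theta0, data


@pytest.fixture(scope="session")
def phenotype_fit():
    """Fitted phenotype baseline shared by the design-module tests."""
    model, theta = phenotype_model()
    times = np.concatenate([CONTROL_TIMES, TREATED_TIMES])
    conditions = ["control"] * 4 + ["treated"] * 2
    spec = ObjectiveSpec(kind="log10_sum_of_squares")
    data = generate_model_baseline(
        model, theta, times, conditions, noise_sd=0.05, seed=7, log10_noise=True
    )
    fit = correct_mle(model, data, theta, spec)
    state = build_continuation_state(model, fit.theta, data, spec)
    return model, theta, data, spec, fit, state
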