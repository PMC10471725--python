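"""Pre-configured reference studies for the built-in models.

Each function assembles one of the package's reference experiments from a
single seed: the two-channel viral oracle study (used to validate the
data->parameter Jacobian against refit derivatives), the stepwise
viral-load perturbation study (predictor vs refit under half-normal data
shifts), the phenotype-model perturbation sequence (iterated
predictor-corrector continuation), and the phenotype candidate-measurement
ranking (experimental design).  Tests and the command-line entry
points share these definitions, so every reported number traces to
one seeded recipe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import seed_stream
from .continuation import (
    ContinuationState,
    CorrectionResult,
    build_continuation_state,
    correct_mle,
)
from .data import CalibrationData
from .model import ModelSpec
from .models.phenotype import CONTROL_TIMES, TREATED_TIMES, phenotype_model
from .models.viral import REFERENCE_TIMES, viral_model
from .objective import ObjectiveSpec
from .parameters import ParameterVector
from .synthetic import generate_model_baseline, generate_viral_baseline, perturb_absolute, perturb_norm_scaled

__all__ = [
    "FittedStudy",
    "viral_oracle_study",
    "viral_stepwise_perturbations",
    "phenotype_baseline",
    "phenotype_sequence",
    "PHENOTYPE_CONSTRAINTS",
    "PHENOTYPE_CANDIDATE_TIMES",
]

#: ordering constraints of the six-point phenotype design: the treated
#: day-4 and day-6 counts cannot exceed their control counterparts
PHENOTYPE_CONSTRAINTS = ((4, 2), (5, 3))

#: candidate additional measurement times (days) in the treated condition
PHENOTYPE_CANDIDATE_TIMES = (3.1, 3.2, 3.3, 3.4, 3.5, 5.0, 7.0)

#: log10-scale noise SD of the oracle study's two assay channels
ORACLE_NOISE_SD = 0.1


@dataclass
class FittedStudy:
    """A model, its generating truth, seeded data, the fitted MLE and state."""

    model: ModelSpec
    theta_true: ParameterVector
    data: CalibrationData
    spec: ObjectiveSpec
    fit: CorrectionResult
    state: ContinuationState


def viral_oracle_study(seed: int = 1) -> FittedStudy:
    """Two-channel viral study: log10 viral load + log10 CD4 count.

    Both channels are sampled at the reference schedule with log10-scale
    Gaussian noise (SD 0.1).  The CD4 channel resolves the target-cell
    parameters that viral load alone leaves practically unidentifiable,
    giving an interior, well-conditioned MLE -- the regime in which the
    data->parameter Jacobian can be validated against refit derivatives.
    """
    model, theta = viral_model()
    times = np.concatenate([REFERENCE_TIMES, REFERENCE_TIMES])
    conditions = ["viral_load"] * len(REFERENCE_TIMES) + ["cd4"] * len(
        REFERENCE_TIMES
    )
    spec = ObjectiveSpec()
    data = generate_model_baseline(
        model, theta, times, conditions, noise_sd=ORACLE_NOISE_SD,
        seed=seed_stream(seed, "viral_oracle"),
    )
    fit = correct_mle(model, data, theta, spec)
    state = build_continuation_state(model, fit.theta, data, spec)
    return FittedStudy(model, theta, data, spec, fit, state)


def viral_stepwise_perturbations(
    seed: int = 1, h_steps: tuple[float, ...] = (0.1, -0.1, 0.2, -0.2)
) -> tuple[FittedStudy, list[CalibrationData]]:
    """Single-channel stepwise study: baseline plus half-normal shifts.

    The baseline is the reduced 8-point log10 viral-load schedule with
    Gaussian noise of variance 0.15; each perturbed set shifts every
    point by h_step |eps| (all points up for positive h_step, all down
    for negative).
    """
    model, theta = viral_model()
    spec = ObjectiveSpec()
    data = generate_viral_baseline(
        model, theta, REFERENCE_TIMES, sigma2=0.15,
        seed=seed_stream(seed, "viral_baseline"),
    )
    fit = correct_mle(model, data, theta, spec)
    state = build_continuation_state(model, fit.theta, data, spec)
    study = FittedStudy(model, theta, data, spec, fit, state)
    perturbed = [
        perturb_absolute(data, h, seed=seed_stream(seed, f"viral_hstep:{i}"))
        for i, h in enumerate(h_steps)
    ]
    return study, perturbed


def phenotype_baseline(seed: int = 1, noise_sd: float = 0.05) -> FittedStudy:
    """Six-point two-condition phenotype baseline and its fitted state.

    Control counts at days 0, 2, 4, 6 and treated counts at days 4, 6,
    with multiplicative log10-scale noise; objective compares log10
    populations.
    """
    model, theta = phenotype_model()
    times = np.concatenate([CONTROL_TIMES, TREATED_TIMES])
    conditions = ["control"] * len(CONTROL_TIMES) + ["treated"] * len(TREATED_TIMES)
    spec = ObjectiveSpec(kind="log10_sum_of_squares")
    data = generate_model_baseline(
        model, theta, times, conditions, noise_sd=noise_sd,
        seed=seed_stream(seed, "phenotype_baseline"), log10_noise=True,
    )
    fit = correct_mle(model, data, theta, spec)
    state = build_continuation_state(model, fit.theta, data, spec)
    return FittedStudy(model, theta, data, spec, fit, state)


def phenotype_sequence(
    study: FittedStudy, seed: int = 1, h_step: float = 0.07, n_steps: int = 10
) -> list[CalibrationData]:
    """The j = 1..n norm-scaled perturbation sequence of the phenotype data.

    One standard-normal draw (fixed by the seed) is rescaled so that the
    log10-space displacement of set j is (0.05 + j h_step) times the
    baseline log10 norm -- the same noise pattern growing coherently,
    which is the regime an iterated continuation steps through.  The
    treated-vs-control ordering constraints are enforced throughout.
    """
    return [
        perturb_norm_scaled(
            study.data, j, h_step,
            seed=seed_stream(seed, "phenotype_sequence"),
            constraints=PHENOTYPE_CONSTRAINTS,
        )
        for j in range(1, n_steps + 1)
    ]
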