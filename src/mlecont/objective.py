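"""Weighted least-squares objective (negative log-likelihood up to constants).

For Gaussian measurement noise with fixed, known sigma_i the negative
log-likelihood reduces, after dropping additive constants, to

    G(theta, phi) = sum_i (y_i(theta) - phi_i)^2 / sigma_i^2.

The ``log10_sum_of_squares`` variant applies the same form to
log10-transformed observables and data, the convention for viral-load and
cell-count measurements spanning orders of magnitude.  All derivative
machinery (gradient, Hessian, mixed partial) operates on this smooth
quadratic form; display-only square-rooted values are left to callers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import CalibrationData
from .model import ModelSpec, simulate_observables
from .parameters import ParameterVector

__all__ = ["ObjectiveSpec", "objective", "residuals", "transform"]

_KINDS = ("weighted_sum_of_squares", "log10_sum_of_squares")


@dataclass(frozen=True)
class ObjectiveSpec:
    """Which least-squares objective to minimise.

    ``constant_terms_dropped`` is always true: the log(sqrt(2 pi sigma^2))
    terms do not influence the minimiser and are omitted.
    """

    kind: str = "weighted_sum_of_squares"
    constant_terms_dropped: bool = True

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"objective kind must be one of {_KINDS}")


def transform(values: np.ndarray, spec: ObjectiveSpec) -> np.ndarray:
    """Apply the objective's observable-space transform."""
    if spec.kind == "log10_sum_of_squares":
        values = np.asarray(values, dtype=float)
        if np.any(values <= 0):
            raise ValueError("log10 objective requires strictly positive values")
        return np.log10(values)
    return np.asarray(values, dtype=float)


def residuals(
    y: np.ndarray, data: CalibrationData, spec: ObjectiveSpec
) -> np.ndarray:
    """Weighted residual vector r_i = (T(y_i) - T(phi_i)) / sigma_i."""
    return (transform(y, spec) - transform(data.values, spec)) / data.noise_scales


def objective(
    model: ModelSpec,
    theta: ParameterVector,
    data: CalibrationData,
    spec: ObjectiveSpec | None = None,
) -> float:
    """G(theta, phi): weighted sum of squared residuals; zero iff perfect fit.

    Invariant to reordering of data rows.  Increments the
    objective-evaluation counter (and, through the simulation, the
    model-simulation counter).
    """
    spec = spec or ObjectiveSpec()
    y = simulate_observables(model, theta, data)
    model.counters.objective_evaluations += 1
    r = residuals(y, data, spec)
    return float(r @ r)
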