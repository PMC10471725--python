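"""Synthetic phenotype-switching tumour growth model (NSCLC analog).

A two-compartment ODE for drug-sensitive (A) and drug-tolerant (B)
non-small-cell lung cancer populations sharing a logistic carrying
capacity, with an Allee-type cooperation boost on the tolerant phenotype
and a treatment switch that raises the sensitive death rate from day 3
onward in the treated condition:

    dA/dt = r_A (1 - N/K) A              - d_A(t) A
    dB/dt = r_B (1 - N/K) f(B) B         - d_B B,      N = A + B
    f(B)  = 1 + allee_strength * B / (allee_half + B)
    d_A(t) = d_A  untreated;  d_A_max  during treatment (t >= 3 d, treated)

The observable is the total population N(t), compared to data on the
log10 scale.  The fitted parameter vector is [r_A, r_B, d_A (= d_B),
d_A_max]; carrying capacity, Allee constants and the inoculum are fixed
structural constants.

This module is a synthetic stand-in: it reproduces the structure of the
published age-structured phenotype-switching model (logistic competition,
same-phenotype cooperation, day-3 treatment switch, six-point two-condition
calibration design) but its constants and reference parameters are chosen
here, not transcribed from the original calibration, whose auxiliary
constants and in-vitro data are not redistributed.  All baselines are
generated from this model's own reference truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..model import ModelSpec
from ..parameters import ParameterVector

__all__ = [
    "PhenotypeConstants",
    "REFERENCE_THETA",
    "CONTROL_TIMES",
    "TREATED_TIMES",
    "phenotype_model",
]

PARAMETER_NAMES = ("r_A", "r_B", "d_A", "d_A_max")

#: reference truth for the fitted vector [r_A, r_B, d_A=d_B, d_A_max] (per day)
REFERENCE_VALUES = np.array([0.9, 0.5, 0.15, 1.6])

LOWER = np.array([1e-3, 1e-3, 1e-3, 1e-3])
UPPER = np.array([5.0, 5.0, 5.0, 10.0])

REFERENCE_THETA = ParameterVector(REFERENCE_VALUES, PARAMETER_NAMES, LOWER, UPPER)

#: six-point calibration design: four control + two treated measurements;
#: treatment starts day 3, so treated rows are bounded above by their
#: control counterparts
CONTROL_TIMES = np.array([0.0, 2.0, 4.0, 6.0])
TREATED_TIMES = np.array([4.0, 6.0])


@dataclass(frozen=True)
class PhenotypeConstants:
    """Fixed structural constants (not fitted)."""

    carrying_capacity: float = 1e4  # cells
    allee_strength: float = 1.0  # dimensionless boost amplitude
    allee_half: float = 100.0  # cells at half-maximal cooperation
    A0: float = 90.0  # sensitive inoculum, cells
    B0: float = 10.0  # tolerant inoculum, cells
    treatment_start: float = 3.0  # days


def phenotype_model(
    constants: PhenotypeConstants | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> tuple[ModelSpec, ParameterVector]:
    """Build the phenotype-switching model; returns (model, reference theta)."""
    k = constants or PhenotypeConstants()

    def rhs(x, t, theta, condition):
        r_A, r_B, d_A, d_A_max = theta.values
        A, B = x
        N = A + B
        logistic = 1.0 - N / k.carrying_capacity
        allee = 1.0 + k.allee_strength * B / (k.allee_half + B)
        death_A = (
            d_A_max
            if (condition == "treated" and t >= k.treatment_start)
            else d_A
        )
        return np.array(
            [
                r_A * logistic * A - death_A * A,
                r_B * logistic * allee * B - d_A * B,  # d_B tied to d_A
            ]
        )

    def jac(x, t, theta, condition):
        r_A, r_B, d_A, d_A_max = theta.values
        A, B = x
        N = A + B
        K = k.carrying_capacity
        logistic = 1.0 - N / K
        allee = 1.0 + k.allee_strength * B / (k.allee_half + B)
        dallee = k.allee_strength * k.allee_half / (k.allee_half + B) ** 2
        death_A = (
            d_A_max
            if (condition == "treated" and t >= k.treatment_start)
            else d_A
        )
        return np.array(
            [
                [r_A * logistic - r_A * A / K - death_A, -r_A * A / K],
                [
                    -r_B * allee * B / K,
                    r_B * (logistic * (allee + dallee * B) - allee * B / K) - d_A,
                ],
            ]
        )

    def init(theta, condition):
        return np.array([k.A0, k.B0])

    def observable(states, times, theta, condition):
        N = states[0] + states[1]
        if np.any(N < 0):
            raise ValueError("total population went negative")
        return N

    def breakpoints(theta, condition):
        return (k.treatment_start,) if condition == "treated" else ()

    model = ModelSpec(
        rhs=rhs,
        initial_state=init,
        observable=observable,
        name="nsclc",
        rtol=rtol,
        atol=atol,
        breakpoints=breakpoints,
        jac=jac,
    )
    return model, REFERENCE_THETA
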