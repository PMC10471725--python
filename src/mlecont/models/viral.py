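"""Target-cell-limited viral dynamics model (HIV-1).

States: uninfected target cells T, infected cells I, free virus V.

    dT/dt = lambda - beta T V - d T
    dI/dt = beta T V - delta I
    dV/dt = delta N I - c V      (equivalently p I - c V with p = delta N)

Target cells are produced at rate lambda and cleared at rate d; infection
proceeds at rate beta per virion per cell; infected cells are cleared at
rate delta, each releasing a burst of N virions; free virus is cleared at
rate c.  The observable is log10 V(t), the standard scale for clinical
viral-load measurements, so the natural objective is the plain sum of
squares on that scale.

Initial conditions are treated as fixed and known: with known (T0, I0, V0)
all six parameters (beta, d, delta, c, N, lambda) are identifiable.  The
reference parameter set used throughout is
beta=2e-5, d=0.15, delta=0.55, c=5.5, N=900, lambda=80 (per day / per
virion units), for which the basic reproduction number
R0 = lambda beta N / (d c) ~ 1.745 exceeds one, so infection grows from a
small inoculum toward a chronic set point.
"""

from __future__ import annotations

import numpy as np

from ..model import ModelSpec
from ..parameters import ParameterVector

__all__ = [
    "REFERENCE_THETA",
    "REFERENCE_TIMES",
    "DEFAULT_INITIAL_STATE",
    "viral_model",
    "basic_reproduction_number",
]

PARAMETER_NAMES = ("beta", "d", "delta", "c", "N", "lambda")

#: condition label selecting the log10 CD4+ T-cell observable channel;
#: any other label observes log10 viral load
CD4_CONDITION = "cd4"

#: reference parameter values (identifiability study ordering)
REFERENCE_VALUES = np.array([2e-5, 0.15, 0.55, 5.5, 900.0, 80.0])

#: sampling times (days) for the reduced calibration schedule
REFERENCE_TIMES = np.array([0.4, 1.0, 8.0, 14.0, 20.0, 36.0, 46.0, 58.0])

#: fixed known initial conditions (T0, I0, V0): an established infection
#: observed from a high viral load, so the early samples (0.4, 1 d) see the
#: fast virion-clearance transient and the later samples the set point
DEFAULT_INITIAL_STATE = (600.0, 30.0, 1e5)

# biologically plausible bounds: one order of magnitude around reference
LOWER = REFERENCE_VALUES / 10.0
UPPER = REFERENCE_VALUES * 10.0

REFERENCE_THETA = ParameterVector(REFERENCE_VALUES, PARAMETER_NAMES, LOWER, UPPER)


def basic_reproduction_number(theta: ParameterVector) -> float:
    """R0 = lambda beta N / (d c)."""
    th = theta.as_dict()
    return th["lambda"] * th["beta"] * th["N"] / (th["d"] * th["c"])


def viral_rhs(x: np.ndarray, t: float, theta: ParameterVector, condition: str):
    beta, d, delta, c, N, lam = theta.values
    T, I, V = x
    infection = beta * T * V
    return np.array(
        [lam - infection - d * T, infection - delta * I, delta * N * I - c * V]
    )


def viral_jac(x: np.ndarray, t: float, theta: ParameterVector, condition: str):
    beta, d, delta, c, N, lam = theta.values
    T, I, V = x
    return np.array(
        [
            [-beta * V - d, 0.0, -beta * T],
            [beta * V, -delta, beta * T],
            [0.0, delta * N, -c],
        ]
    )


def viral_model(
    initial_state: tuple[float, float, float] = DEFAULT_INITIAL_STATE,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> tuple[ModelSpec, ParameterVector]:
    """Build the viral dynamics model with fixed known initial conditions.

    Returns the model and the reference parameter vector (with bounds).
    """
    x0 = np.asarray(initial_state, dtype=float)
    if np.any(x0 < 0):
        raise ValueError("initial conditions must be nonnegative")

    def init(theta, condition):
        return x0.copy()

    def observable(states, times, theta, condition):
        # two measurement channels, selected by the condition label:
        # log10 viral load (default) or log10 CD4+ T-cell count --
        # clinical studies routinely report both, and the T channel
        # resolves the (beta, lambda, d) compensation that viral load
        # alone leaves sloppy.
        # floor at integrator-noise scale: states can graze zero during
        # optimizer excursions; the huge negative log10 acts as a smooth
        # penalty steering the fit back to positive trajectories
        state = states[0] if condition == CD4_CONDITION else states[2]
        return np.log10(np.maximum(state, 1e-12))

    model = ModelSpec(
        rhs=viral_rhs,
        initial_state=init,
        observable=observable,
        name="viral",
        rtol=rtol,
        atol=atol,
        jac=viral_jac,
    )
    return model, REFERENCE_THETA
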