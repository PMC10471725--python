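"""Dynamical model specification and simulation.

A model is an ODE system dx/dt = f(x, t, theta, condition) with a
parameter-dependent initial condition x(0) = x0(theta, condition) and an
observable map h taking the state trajectory at the requested times to one
real value per measurement row.  Conditions select experimental regimes
(e.g. drug on/off); each condition is integrated once per simulation call.

Every simulation is counted.  The continuation method's efficiency claims
are evaluation-count comparisons, so counters are first-class here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .data import CalibrationData
from .parameters import ParameterVector

__all__ = ["ModelSpec", "EvalCounters", "SimulationError", "simulate_observables"]


class SimulationError(RuntimeError):
    """ODE integration failed (stiff blow-up or non-finite state)."""


@dataclass
class EvalCounters:
    """Running totals of the expensive operations.

    ``model_simulations`` counts calls to :func:`simulate_observables`
    (one forward solve of the model over all conditions);
    ``condition_integrations`` counts individual ODE solves;
    ``objective_evaluations`` counts objective-function evaluations.
    """

    model_simulations: int = 0
    condition_integrations: int = 0
    objective_evaluations: int = 0

    def snapshot(self) -> dict[str, int]:
        return {
            "model_simulations": self.model_simulations,
            "condition_integrations": self.condition_integrations,
            "objective_evaluations": self.objective_evaluations,
        }

    def since(self, before: dict[str, int]) -> dict[str, int]:
        now = self.snapshot()
        return {k: now[k] - before[k] for k in now}

    def reset(self) -> None:
        self.model_simulations = 0
        self.condition_integrations = 0
        self.objective_evaluations = 0


@dataclass
class ModelSpec:
    """A calibratable dynamical system.

    Parameters
    ----------
    rhs : callable ``(x, t, theta, condition) -> dx/dt``
        Right-hand side of the ODE; must be deterministic.
    initial_state : callable ``(theta, condition) -> x(0)``
        Parameter-dependent initial condition.
    observable : callable ``(states, times, theta, condition) -> y``
        Maps the trajectory sampled at ``times`` (array of shape
        ``(n_states, n_times)``) to one observable value per time.  The
        condition label lets one model expose several measurement
        channels (m >= 2 observables flatten into one data table with a
        channel label per row).
    name : str
        Registry key.
    t0 : float
        Integration start time.
    rtol, atol : float
        Integrator tolerances.  Defaults are tight (1e-10 / 1e-12) so that
        integrator noise stays far below finite-difference truncation error.
    breakpoints : callable ``(theta, condition) -> sequence of float``, optional
        Times at which the right-hand side switches discontinuously
        (e.g. treatment start); integration is split there.
    jac : callable ``(x, t, theta, condition) -> d f / d x``, optional
        Analytic state Jacobian, passed to implicit solvers for speed.
    method : str
        ``scipy.integrate.solve_ivp`` method; LSODA handles the stiff
        phases of both built-in models.
    """

    rhs: Callable[[np.ndarray, float, ParameterVector, str], np.ndarray]
    initial_state: Callable[[ParameterVector, str], np.ndarray]
    observable: Callable[
        [np.ndarray, np.ndarray, ParameterVector, str], np.ndarray
    ]
    name: str = "model"
    t0: float = 0.0
    rtol: float = 1e-10
    atol: float = 1e-12
    breakpoints: Callable[[ParameterVector, str], Sequence[float]] | None = None
    jac: Callable[[np.ndarray, float, ParameterVector, str], np.ndarray] | None = None
    method: str = "LSODA"
    counters: EvalCounters = field(default_factory=EvalCounters)

    def _integrate_condition(
        self, theta: ParameterVector, condition: str, times: np.ndarray
    ) -> np.ndarray:
        """Solve one condition, returning states of shape (n, len(times))."""
        x = np.asarray(self.initial_state(theta, condition), dtype=float)
        t_end = float(times[-1])
        if t_end <= self.t0:  # nothing to integrate, all rows at/before t0
            return np.repeat(x[:, None], times.size, axis=1)
        cuts = [self.t0]
        if self.breakpoints is not None:
            cuts += [
                float(b)
                for b in self.breakpoints(theta, condition)
                if self.t0 < b < t_end
            ]
        cuts.append(t_end)

        states = np.empty((x.size, times.size))
        filled = np.zeros(times.size, dtype=bool)
        for a, b in zip(cuts[:-1], cuts[1:]):
            # sample strictly inside (a, b], the final state seeds next leg
            mask = (times > a) & (times <= b) & ~filled
            t_eval = np.unique(np.concatenate([times[mask], [b]]))
            sol = solve_ivp(
                lambda t, s: self.rhs(s, t, theta, condition),
                (a, b),
                x,
                method=self.method,
                t_eval=t_eval,
                rtol=self.rtol,
                atol=self.atol,
                jac=(
                    None
                    if self.jac is None
                    else lambda t, s: self.jac(s, t, theta, condition)
                ),
            )
            if not sol.success or not np.all(np.isfinite(sol.y)):
                raise SimulationError(
                    f"integration of model {self.name!r} failed in condition "
                    f"{condition!r} near t={sol.t[-1] if sol.t.size else a:.4g} "
                    f"at theta={theta.as_dict()}"
                )
            for i in np.flatnonzero(mask):
                j = int(np.searchsorted(sol.t, times[i]))
                states[:, i] = sol.y[:, j]
            filled |= mask
            x = sol.y[:, -1]
        # rows at t <= t0 take the initial state
        at_start = times <= self.t0
        states[:, at_start] = np.asarray(
            self.initial_state(theta, condition), dtype=float
        )[:, None]
        return states


def simulate_observables(
    model: ModelSpec, theta: ParameterVector, data: CalibrationData
) -> np.ndarray:
    """Model observables y_i(theta) at every (time, condition) row of ``data``.

    One ODE solve per condition; returns values in data-row order.
    Increments the model-simulation counter by one and the
    condition-integration counter by one per condition.
    """
    y = np.empty(data.d)
    for condition in data.condition_order:
        rows = data.rows_for(condition)
        states = model._integrate_condition(theta, condition, data.times[rows])
        y_c = np.asarray(
            model.observable(states, data.times[rows], theta, condition),
            dtype=float,
        )
        if y_c.shape != (rows.size,):
            raise ValueError(
                f"observable returned shape {y_c.shape}, expected ({rows.size},)"
            )
        y[rows] = y_c
        model.counters.condition_integrations += 1
    model.counters.model_simulations += 1
    if not np.all(np.isfinite(y)):
        raise SimulationError(
            f"non-finite observable from model {model.name!r} at "
            f"theta={theta.as_dict()}"
        )
    return y
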