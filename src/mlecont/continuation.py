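"""Continuation of maximum-likelihood estimators in calibration-data space.

The MLE theta*(phi) is defined implicitly by the stationarity condition
D_theta G(theta*, phi) = 0.  Where the Hessian H = D^2_theta G (the
observed Fisher information) is invertible, the implicit function theorem
yields the data -> parameter Jacobian

    DPsi = -H^{-1} M,    M = D^2_{theta,phi} G,

so the MLE for perturbed data phi + dphi is predicted to first order by
theta* + DPsi dphi, at zero additional model simulations.  A corrector
(any bounded local least-squares optimiser) refines the prediction when
needed.  Building DPsi from scratch costs at most 2p(p+2) model
simulations: 2p for the sensitivities behind M and 2p(p+1) objective
evaluations for H.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .data import CalibrationData
from .fd import (
    FDConfig,
    hessian_fd,
    hessian_least_squares,
    mixed_partial,
    objective_gradient,
    sensitivity_matrix,
    transform_derivative,
)
from .model import ModelSpec, simulate_observables
from .objective import ObjectiveSpec, objective, residuals, transform
from .parameters import ParameterVector

__all__ = [
    "ContinuationState",
    "CorrectionResult",
    "PathStep",
    "SingularHessianError",
    "compute_dpsi",
    "build_continuation_state",
    "predict_mle",
    "correct_mle",
    "continuation_path",
    "MLEContinuation",
]

#: above this condition number of H, DPsi is numerically meaningless and
#: signals practical unidentifiability
DEFAULT_COND_THRESHOLD = 1e10


class SingularHessianError(np.linalg.LinAlgError):
    """Hessian too ill-conditioned to invert: practical unidentifiability."""


@dataclass(frozen=True)
class ContinuationState:
    """An MLE together with the local data-space calculus around it.

    Fields: the MLE ``theta_star`` at data ``phi`` (= ``data``), the
    observed Fisher information ``hessian`` (p x p), the mixed partial
    ``mixed_partial`` (p x d), the data->parameter Jacobian ``dpsi``
    (p x d) solving H dpsi = -M, and the evaluation counts spent building
    them.
    """

    theta_star: ParameterVector
    data: CalibrationData
    hessian: np.ndarray
    mixed_partial: np.ndarray
    dpsi: np.ndarray
    #: Jacobian with respect to the objective's transformed data T(phi)
    #: (equal to ``dpsi`` for identity transforms); the predictor
    #: linearises in T(phi), the variable the likelihood actually sees
    dpsi_transformed: np.ndarray = None  # type: ignore[assignment]
    objective_spec: "ObjectiveSpec" = None  # type: ignore[assignment]
    eval_counts: dict[str, int] = field(default_factory=dict)
    #: parameters free to move; False marks components pinned at an active
    #: bound, whose DPsi rows are zero (continuation happens on the free
    #: subspace of the bound-constrained stationarity conditions)
    free_mask: np.ndarray | None = None


@dataclass(frozen=True)
class CorrectionResult:
    """Outcome of a corrector run."""

    theta: ParameterVector
    objective_value: float
    eval_counts: dict[str, int]
    converged: bool
    optimality: float  # sup-norm of the (scaled) gradient at the solution


def compute_dpsi(
    H: np.ndarray,
    M: np.ndarray,
    cond_threshold: float = DEFAULT_COND_THRESHOLD,
    parameter_names: tuple[str, ...] | None = None,
) -> np.ndarray:
    """Solve H DPsi = -M for the data->parameter Jacobian (p x d).

    Never forms H^{-1} explicitly.  Raises :class:`SingularHessianError`
    when cond(H) exceeds ``cond_threshold``, naming the near-null
    eigendirection -- the practical-unidentifiability signal.
    """
    H = np.asarray(H, dtype=float)
    M = np.asarray(M, dtype=float)
    p = H.shape[0]
    if H.shape != (p, p) or M.shape[0] != p:
        raise ValueError("H must be p x p and M p x d")
    # conditioning is assessed on the Jacobi-equilibrated Hessian so that
    # parameter-unit artifacts (rates spanning many orders of magnitude)
    # do not masquerade as unidentifiability
    diag = np.abs(np.diag(H))
    if np.any(diag == 0):
        scale = np.ones(p)
    else:
        scale = 1.0 / np.sqrt(diag)
    Hs = H * scale[:, None] * scale[None, :]
    eigvals, eigvecs = scipy.linalg.eigh(Hs)
    amag = np.abs(eigvals)
    if amag.min() == 0 or amag.max() / amag.min() > cond_threshold:
        null_vec = eigvecs[:, int(np.argmin(amag))]
        names = parameter_names or tuple(f"theta_{i}" for i in range(p))
        dominant = names[int(np.argmax(np.abs(null_vec)))]
        raise SingularHessianError(
            f"Hessian condition number {amag.max() / max(amag.min(), 1e-300):.3g} "
            f"(after diagonal equilibration) exceeds {cond_threshold:.3g}; "
            f"near-null direction {np.round(null_vec, 4)} (dominated by "
            f"{dominant!r}) indicates practical unidentifiability"
        )
    # solve the equilibrated system, then undo the scaling
    X = scipy.linalg.solve(Hs, -(M * scale[:, None]), assume_a="sym")
    return X * scale[:, None]


def build_continuation_state(
    model: ModelSpec,
    theta_star: ParameterVector,
    data: CalibrationData,
    spec: ObjectiveSpec | None = None,
    fd: FDConfig | None = None,
    cond_threshold: float = DEFAULT_COND_THRESHOLD,
    hessian: np.ndarray | str = "least_squares",
) -> ContinuationState:
    """Assemble H, M and DPsi at a (presumed) MLE.

    Costs at most 2p(p+2) model simulations in total: 2p for the
    sensitivities plus the Hessian stencils.  ``hessian`` selects the
    Hessian route: ``"least_squares"`` (default) uses the residual-split
    scheme, which reuses the sensitivity evaluations and is far more
    accurate near a good fit; ``"objective_fd"`` double-differences the
    objective; a pre-computed array (e.g. recycled from an optimiser) is
    used as-is.
    """
    spec = spec or ObjectiveSpec()
    fd = fd or FDConfig()
    before = model.counters.snapshot()
    if isinstance(hessian, str) and hessian == "least_squares":
        H, S = hessian_least_squares(model, theta_star, data, spec, fd)
    else:
        S = sensitivity_matrix(model, theta_star, data, fd, spec)
        if isinstance(hessian, str):
            if hessian != "objective_fd":
                raise ValueError(
                    "hessian must be 'least_squares', 'objective_fd' or an array"
                )
            H = hessian_fd(model, theta_star, data, spec, fd)
        else:
            H = hessian
    tprime = transform_derivative(data.values, spec)
    M_t = mixed_partial(S, data.noise_scales)  # wrt transformed data T(phi)
    M = M_t * tprime  # wrt the raw data values
    H = np.asarray(H, dtype=float)
    # parameters resting on an active bound are pinned there by the
    # constrained fit; continuation acts on the free subspace and their
    # DPsi rows are zero (a data perturbation cannot move them off the
    # bound to first order)
    nominal = np.maximum(
        fd.relative_step * np.abs(theta_star.values), fd.absolute_step_floor
    )
    free = (theta_star.values - theta_star.lower > nominal) & (
        theta_star.upper - theta_star.values > nominal
    )
    if not np.any(free):
        raise SingularHessianError(
            "every parameter is pinned at a bound; no free subspace remains"
        )
    dpsi_t = np.zeros_like(M_t)
    idx = np.flatnonzero(free)
    dpsi_t[np.ix_(idx, np.arange(data.d))] = compute_dpsi(
        H[np.ix_(idx, idx)],
        M_t[idx],
        cond_threshold,
        tuple(theta_star.names[i] for i in idx),
    )
    return ContinuationState(
        theta_star=theta_star,
        data=data,
        hessian=H,
        mixed_partial=M,
        dpsi=dpsi_t * tprime,
        dpsi_transformed=dpsi_t,
        objective_spec=spec,
        eval_counts=model.counters.since(before),
        free_mask=free,
    )


def predict_mle(state: ContinuationState, delta_phi: np.ndarray) -> ParameterVector:
    """First-order predictor: theta* + DPsi dphi, at zero model simulations.

    For objectives that compare transformed data (log10), the expansion is
    taken in the transformed data space T(phi) -- the variable the
    likelihood actually depends on -- so multiplicative data perturbations
    are handled at their natural (log) scale.  For identity transforms
    this is the plain theta* + DPsi dphi.

    Components leaving the admissible box Omega are clipped back with a
    warning (the Taylor expansion is unconstrained; Omega must hold
    downstream).
    """
    delta_phi = np.asarray(delta_phi, dtype=float)
    if delta_phi.shape != (state.data.d,):
        raise ValueError(f"delta_phi must have length d={state.data.d}")
    spec = state.objective_spec or ObjectiveSpec()
    delta_t = transform(state.data.values + delta_phi, spec) - transform(
        state.data.values, spec
    )
    raw = state.theta_star.values + state.dpsi_transformed @ delta_t
    theta = state.theta_star
    if np.any(raw < theta.lower) or np.any(raw > theta.upper):
        outside = [
            theta.names[i]
            for i in range(theta.p)
            if raw[i] < theta.lower[i] or raw[i] > theta.upper[i]
        ]
        warnings.warn(
            f"predicted MLE left Omega in component(s) {outside}; clipped",
            stacklevel=2,
        )
    return theta.with_values(raw, clip=True)


def correct_mle(
    model: ModelSpec,
    data: CalibrationData,
    start: ParameterVector,
    spec: ObjectiveSpec | None = None,
    fd: FDConfig | None = None,
    xtol: float = 1e-14,
    ftol: float = 1e-14,
    gtol: float = 1e-12,
    max_nfev: int | None = None,
    polish_iterations: int = 3,
) -> CorrectionResult:
    """Corrector: bounded local least-squares refinement from ``start``.

    Runs a trust-region-reflective minimisation of the weighted residual
    vector, with the package's central-difference sensitivity matrix as
    the Jacobian (accurate steps matter: noisy Jacobians stall the
    optimiser far from stationarity).  The optimiser's iterate is then
    polished by up to ``polish_iterations`` damped Newton steps on the
    free parameter subspace, using the finite-difference Hessian and
    sensitivity gradient; trust-region stopping rules leave a residual
    wobble (~1e-4 relative) along flat likelihood valleys that the
    Newton polish removes, which matters when differentiating refits.

    Contract: the returned objective never exceeds the objective at
    ``start``; on optimizer non-convergence the best iterate is returned
    flagged ``converged=False``.
    """
    spec = spec or ObjectiveSpec()
    fd = fd or FDConfig()
    before = model.counters.snapshot()

    def fun(x: np.ndarray) -> np.ndarray:
        y = simulate_observables(model, start.with_values(x, clip=True), data)
        model.counters.objective_evaluations += 1
        return residuals(y, data, spec)

    def jac(x: np.ndarray) -> np.ndarray:
        S = sensitivity_matrix(
            model, start.with_values(x, clip=True), data, fd, spec
        )
        return (S / data.noise_scales).T

    x_scale = np.where(np.abs(start.values) > 0, np.abs(start.values), 1.0)
    res = least_squares(
        fun,
        start.values,
        jac=jac,
        bounds=(start.lower, start.upper),
        method="trf",
        x_scale=x_scale,
        xtol=xtol,
        ftol=ftol,
        gtol=gtol,
        max_nfev=max_nfev,
    )
    theta = start.with_values(res.x, clip=True)
    best_obj = 2.0 * float(res.cost)
    theta, best_obj = _newton_polish(
        model, theta, data, spec, fd, best_obj, polish_iterations
    )
    return CorrectionResult(
        theta=theta,
        objective_value=best_obj,
        eval_counts=model.counters.since(before),
        converged=bool(res.status > 0),
        optimality=float(res.optimality),
    )


def _newton_polish(
    model: ModelSpec,
    theta: ParameterVector,
    data: CalibrationData,
    spec: ObjectiveSpec,
    fd: FDConfig,
    current_objective: float,
    iterations: int,
) -> tuple[ParameterVector, float]:
    """Damped Newton steps on the free subspace.

    Steps are accepted up to a noise-level increase of the objective: the
    wobble this polish removes lies along valley floors where objective
    differences are at the integrator-noise level, so strict descent
    would reject the very correction being applied.
    """
    for _ in range(iterations):
        nominal = np.maximum(
            fd.relative_step * np.abs(theta.values), fd.absolute_step_floor
        )
        free = (theta.values - theta.lower > nominal) & (
            theta.upper - theta.values > nominal
        )
        if not np.any(free):
            break
        grad = objective_gradient(model, theta, data, spec, fd)
        H, _ = hessian_least_squares(model, theta, data, spec, fd)
        idx = np.flatnonzero(free)
        try:
            step_f = scipy.linalg.solve(
                H[np.ix_(idx, idx)], -grad[idx], assume_a="sym"
            )
        except scipy.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step_f)):
            break
        accepted = False
        damping = 1.0
        for _ in range(4):  # backtracking
            trial_values = theta.values.copy()
            trial_values[idx] += damping * step_f
            trial = theta.with_values(trial_values, clip=True)
            trial_obj = objective(model, trial, data, spec)
            if trial_obj < current_objective + 1e-9 * (1.0 + abs(current_objective)):
                theta, current_objective = trial, trial_obj
                accepted = True
                break
            damping *= 0.25
        if not accepted:
            break
    return theta, current_objective


@dataclass(frozen=True)
class PathStep:
    """One step of an iterated continuation through a data sequence."""

    index: int
    state: ContinuationState  # state at this data set (at predicted or corrected MLE)
    predicted: ParameterVector | None
    objective_naive: float | None  # previous theta* evaluated on this data
    objective_predicted: float | None
    objective_value: float  # at this step's theta_star
    correction: CorrectionResult | None
    cumulative_counts: dict[str, int]


def continuation_path(
    model: ModelSpec,
    theta0: ParameterVector,
    datasets: list[CalibrationData],
    mode: str = "predict_and_correct",
    spec: ObjectiveSpec | None = None,
    fd: FDConfig | None = None,
    cond_threshold: float = DEFAULT_COND_THRESHOLD,
) -> list[PathStep]:
    """Iterated predictor(-corrector) along a sequence of data sets.

    ``datasets[0]`` is the data at which ``theta0`` is the (initial) MLE;
    each later step predicts from the state at the previous data set,
    using theta*(phi^{j-1}) + DPsi(phi^{j-1}) (phi^j - phi^{j-1}), and in
    ``predict_and_correct`` mode refines the prediction before moving on.
    All data sets must share times, conditions and noise scales.
    """
    if mode not in ("predict_only", "predict_and_correct"):
        raise ValueError("mode must be 'predict_only' or 'predict_and_correct'")
    spec = spec or ObjectiveSpec()
    fd = fd or FDConfig()
    base = datasets[0]
    for ds in datasets[1:]:
        if (
            not np.array_equal(ds.times, base.times)
            or ds.conditions != base.conditions
            or not np.array_equal(ds.noise_scales, base.noise_scales)
        ):
            raise ValueError(
                "all data sets in a continuation path must share times, "
                "conditions and noise scales (only values may differ)"
            )

    t0_counts = model.counters.snapshot()
    steps: list[PathStep] = []
    state = build_continuation_state(
        model, theta0, base, spec, fd, cond_threshold
    )
    steps.append(
        PathStep(
            index=0,
            state=state,
            predicted=None,
            objective_naive=None,
            objective_predicted=None,
            objective_value=objective(model, theta0, base, spec),
            correction=None,
            cumulative_counts=model.counters.since(t0_counts),
        )
    )
    for j, ds in enumerate(datasets[1:], start=1):
        delta_phi = ds.values - state.data.values
        predicted = predict_mle(state, delta_phi)
        obj_naive = objective(model, state.theta_star, ds, spec)
        obj_pred = objective(model, predicted, ds, spec)
        correction = None
        if mode == "predict_and_correct":
            correction = correct_mle(model, ds, predicted, spec)
            theta_here = correction.theta
            obj_here = correction.objective_value
        else:
            theta_here = predicted
            obj_here = obj_pred
        state = build_continuation_state(
            model, theta_here, ds, spec, fd, cond_threshold
        )
        steps.append(
            PathStep(
                index=j,
                state=state,
                predicted=predicted,
                objective_naive=obj_naive,
                objective_predicted=obj_pred,
                objective_value=obj_here,
                correction=correction,
                cumulative_counts=model.counters.since(t0_counts),
            )
        )
    return steps


class MLEContinuation(BaseEstimator):
    """Estimator facade for MLE continuation in data space.

    ``fit`` locates (or accepts) the MLE on a calibration data set and
    builds the local continuation state; ``predict`` maps perturbed data
    to first-order predicted MLEs at zero additional simulations;
    ``correct`` runs the optimizer-backed corrector.

    Parameters
    ----------
    model : ModelSpec
        The dynamical model to calibrate.
    objective_kind : str
        ``"weighted_sum_of_squares"`` or ``"log10_sum_of_squares"``.
    relative_step, absolute_step_floor, hessian_diagonal_scheme :
        Finite-difference settings (see :class:`~mlecont.fd.FDConfig`).
    cond_threshold : float
        Hessian condition-number limit beyond which the data-space
        Jacobian is refused (practical unidentifiability).
    refit : bool
        If true (default), ``fit`` refines ``theta0`` with the corrector
        before building the state; if false, ``theta0`` is trusted as the
        MLE.

    Attributes
    ----------
    theta_star_ : ParameterVector
        The fitted MLE.
    state_ : ContinuationState
        Hessian, mixed partial and DPsi at the MLE.
    dpsi_ : ndarray of shape (p, d)
        Data->parameter Jacobian.
    hessian_ : ndarray of shape (p, p)
        Observed Fisher information.
    objective_value_ : float
        G(theta*, phi) at the fit.
    eval_counts_ : dict
        Simulations/objective evaluations spent during fit.
    """

    def __init__(
        self,
        model: ModelSpec = None,
        objective_kind: str = "weighted_sum_of_squares",
        relative_step: float = 1e-4,
        absolute_step_floor: float = 1e-8,
        hessian_diagonal_scheme: str = "central",
        cond_threshold: float = DEFAULT_COND_THRESHOLD,
        refit: bool = True,
    ) -> None:
        self.model = model
        self.objective_kind = objective_kind
        self.relative_step = relative_step
        self.absolute_step_floor = absolute_step_floor
        self.hessian_diagonal_scheme = hessian_diagonal_scheme
        self.cond_threshold = cond_threshold
        self.refit = refit

    def _spec(self) -> ObjectiveSpec:
        return ObjectiveSpec(kind=self.objective_kind)

    def _fd(self) -> FDConfig:
        return FDConfig(
            relative_step=self.relative_step,
            absolute_step_floor=self.absolute_step_floor,
            hessian_diagonal_scheme=self.hessian_diagonal_scheme,
        )

    def fit(self, data: CalibrationData, theta0: ParameterVector = None):
        """Locate the MLE on ``data`` starting from ``theta0`` and build DPsi."""
        if self.model is None:
            raise ValueError("MLEContinuation requires a model")
        if theta0 is None:
            raise ValueError("fit requires an initial parameter vector theta0")
        before = self.model.counters.snapshot()
        if self.refit:
            result = correct_mle(self.model, data, theta0, self._spec())
            theta = result.theta
            self.objective_value_ = result.objective_value
            self.correction_ = result
        else:
            theta = theta0
            self.objective_value_ = objective(self.model, theta, data, self._spec())
            self.correction_ = None
        self.state_ = build_continuation_state(
            self.model, theta, data, self._spec(), self._fd(), self.cond_threshold
        )
        self.theta_star_ = theta
        self.dpsi_ = self.state_.dpsi
        self.hessian_ = self.state_.hessian
        self.eval_counts_ = self.model.counters.since(before)
        return self

    def predict(self, data) -> np.ndarray:
        """Predicted MLE value(s) for perturbed data.

        ``data`` may be a single :class:`CalibrationData`, a 1-d array of
        perturbed values, or a 2-d array (one row per perturbed data set);
        returns the corresponding parameter vector(s).
        """
        if not hasattr(self, "state_"):
            raise RuntimeError("MLEContinuation is not fitted")
        base = self.state_.data.values
        if isinstance(data, CalibrationData):
            values = data.values[None, :]
        else:
            values = np.atleast_2d(np.asarray(data, dtype=float))
        out = np.vstack(
            [predict_mle(self.state_, row - base).values for row in values]
        )
        return out[0] if out.shape[0] == 1 else out

    def correct(self, data: CalibrationData) -> CorrectionResult:
        """Predictor-started corrector on a perturbed data set."""
        if not hasattr(self, "state_"):
            raise RuntimeError("MLEContinuation is not fitted")
        start = predict_mle(self.state_, data.values - self.state_.data.values)
        return correct_mle(self.model, data, start, self._spec())
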