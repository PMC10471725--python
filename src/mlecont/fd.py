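"""Finite-difference derivative machinery.

Central-difference local sensitivities d y_i / d theta_n (2p model
simulations), the mixed second partial of the objective with respect to
parameters and data, and the finite-difference Hessian of the objective
(at most 2p(p+1) objective evaluations).  These three pieces are exactly
what the data-space continuation step consumes.

First-derivative steps default to ``max(1e-4 |theta_n|, 1e-8)`` per
parameter: large enough that integrator noise (tolerances 1e-10/1e-12)
stays well below the difference, small enough that truncation error is
negligible for smooth objectives.  Second-derivative stencils use a
coarser step (fourth-root-of-noise scaling); see :class:`FDConfig`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import CalibrationData
from .model import ModelSpec, simulate_observables
from .objective import ObjectiveSpec, objective, residuals, transform
from .parameters import ParameterVector

__all__ = [
    "FDConfig",
    "hessian_least_squares",
    "sensitivity_matrix",
    "mixed_partial",
    "transform_derivative",
    "hessian_fd",
    "objective_gradient",
]


@dataclass(frozen=True)
class FDConfig:
    """Deterministic finite-difference settings.

    ``relative_step`` scales first-derivative steps with each parameter's
    magnitude; ``absolute_step_floor`` protects parameters near zero.
    Second-derivative stencils divide the objective's noise floor by h^2
    rather than h, so their optimal step scales as the fourth root of that
    noise (~(1e-10)^(1/4) with the default integrator tolerances);
    ``hessian_relative_step`` is therefore larger than ``relative_step``.
    ``hessian_diagonal_scheme`` chooses central (default, one order more
    accurate) or forward second differences for the Hessian diagonal.
    """

    relative_step: float = 1e-4
    absolute_step_floor: float = 1e-8
    hessian_relative_step: float = 3e-3
    hessian_absolute_step_floor: float = 1e-8
    hessian_diagonal_scheme: str = "central"

    def __post_init__(self) -> None:
        if min(
            self.relative_step,
            self.absolute_step_floor,
            self.hessian_relative_step,
            self.hessian_absolute_step_floor,
        ) <= 0:
            raise ValueError("finite-difference steps must be strictly positive")
        if self.hessian_diagonal_scheme not in ("central", "forward"):
            raise ValueError("hessian_diagonal_scheme must be 'central' or 'forward'")


def _directional_steps(
    theta: ParameterVector, nominal: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Stencil offsets (minus, plus) per parameter for nominal half-width.

    Central where the box allows; silently one-sided when the parameter
    sits at (or hugs) one bound, which is routine during bounded
    optimisation.  Raises only when a parameter is pinned at both bounds.
    """
    lo_room = theta.values - theta.lower
    hi_room = theta.upper - theta.values
    span = np.minimum(2.0 * nominal, lo_room + hi_room)
    if np.any(span <= 0):
        dead = [theta.names[i] for i in np.flatnonzero(span <= 0)]
        raise ValueError(
            f"finite-difference step clipped to zero for {dead}: parameter "
            "has no room inside its bounds"
        )
    # keep the stencil span ~2h, sliding it off a bound when necessary
    minus = np.minimum(lo_room, span / 2.0)
    plus = np.minimum(hi_room, span - minus)
    minus = np.minimum(lo_room, span - plus)
    return minus, plus


def sensitivity_matrix(
    model: ModelSpec,
    theta: ParameterVector,
    data: CalibrationData,
    fd: FDConfig | None = None,
    spec: ObjectiveSpec | None = None,
) -> np.ndarray:
    """Central-difference sensitivities S[n, i] = d y_i / d theta_n (p x d).

    Uses exactly 2p model simulations.  When an objective spec with a
    log10 transform is supplied, the sensitivities are those of the
    transformed observables (the quantities the objective differentiates).
    """
    fd = fd or FDConfig()
    spec = spec or ObjectiveSpec()
    nominal = np.maximum(
        fd.relative_step * np.abs(theta.values), fd.absolute_step_floor
    )
    minus, plus = _directional_steps(theta, nominal)
    S = np.empty((theta.p, data.d))
    for n in range(theta.p):
        e_plus = np.zeros(theta.p)
        e_minus = np.zeros(theta.p)
        e_plus[n] = plus[n]
        e_minus[n] = minus[n]
        y_plus = transform(
            simulate_observables(model, theta.with_values(theta.values + e_plus), data),
            spec,
        )
        y_minus = transform(
            simulate_observables(
                model, theta.with_values(theta.values - e_minus), data
            ),
            spec,
        )
        S[n] = (y_plus - y_minus) / (plus[n] + minus[n])
    return S


def mixed_partial(
    S: np.ndarray,
    noise_scales: np.ndarray,
    data_transform_derivative: np.ndarray | float = 1.0,
) -> np.ndarray:
    """Mixed partial M[n, i] = d^2 G / d theta_n d phi_i = -2 S[n, i] / sigma_i^2.

    The sigma^2 weight carries the objective's weighting; for sigma == 1
    this is exactly -2 dy/dtheta.  When the objective compares transformed
    data T(phi) (e.g. log10), ``data_transform_derivative`` supplies
    T'(phi_i) per point so that the derivative is taken with respect to
    the raw data values the user perturbs.
    """
    S = np.asarray(S, dtype=float)
    sigma = np.asarray(noise_scales, dtype=float)
    if S.ndim != 2 or sigma.shape != (S.shape[1],):
        raise ValueError("S must be p x d and noise_scales length d")
    return -2.0 * S * np.asarray(data_transform_derivative) / sigma**2


def transform_derivative(values: np.ndarray, spec: ObjectiveSpec) -> np.ndarray:
    """T'(phi): derivative of the objective's data transform at each point."""
    values = np.asarray(values, dtype=float)
    if spec.kind == "log10_sum_of_squares":
        if np.any(values <= 0):
            raise ValueError("log10 objective requires strictly positive values")
        return 1.0 / (values * np.log(10.0))
    return np.ones_like(values)


def hessian_fd(
    model: ModelSpec,
    theta: ParameterVector,
    data: CalibrationData,
    spec: ObjectiveSpec | None = None,
    fd: FDConfig | None = None,
) -> np.ndarray:
    """Finite-difference Hessian H = D^2_theta G (p x p, symmetric).

    Diagonal entries use central (default) or forward second differences;
    off-diagonal entries the four-point mixed stencil
    [G(++) - G(+-) - G(-+) + G(--)] / (4 h_i h_j).  Both stencils are exact
    on quadratics.  Costs at most 2p(p+1) objective evaluations.
    """
    spec = spec or ObjectiveSpec()
    fd = fd or FDConfig()
    nominal = np.maximum(
        fd.hessian_relative_step * np.abs(theta.values),
        fd.hessian_absolute_step_floor,
    )
    minus, plus = _directional_steps(theta, nominal)
    p = theta.p

    def G(delta: np.ndarray) -> float:
        value = objective(model, theta.with_values(theta.values + delta), data, spec)
        if not np.isfinite(value):
            raise FloatingPointError(
                f"non-finite objective at finite-difference stencil point "
                f"theta + {delta}"
            )
        return value

    H = np.empty((p, p))
    g0 = G(np.zeros(p))
    for n in range(p):
        e = np.zeros(p)
        a, b = minus[n], plus[n]
        if fd.hessian_diagonal_scheme == "forward" or min(a, b) < 0.5 * nominal[n]:
            # one-sided three-point second difference on the free side
            direction = 1.0 if b >= a else -1.0
            h = max(a, b) / 2.0
            e[n] = direction * h
            H[n, n] = (G(2 * e) - 2.0 * G(e) + g0) / h**2
        else:
            # unequally spaced three-point stencil {-a, 0, +b}; exact on
            # quadratics for any offsets
            e[n] = 1.0
            H[n, n] = (
                2.0 * (b * G(-a * e) - (a + b) * g0 + a * G(b * e))
                / (a * b * (a + b))
            )
    for i in range(p):
        for j in range(i + 1, p):
            # two-point offsets per parameter; exact on quadratics even
            # when one side collapses onto the centre at an active bound
            lo_i, hi_i = -minus[i], plus[i]
            lo_j, hi_j = -minus[j], plus[j]
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = 1.0
            ej[j] = 1.0
            H[i, j] = H[j, i] = (
                G(hi_i * ei + hi_j * ej)
                - G(hi_i * ei + lo_j * ej)
                - G(lo_i * ei + hi_j * ej)
                + G(lo_i * ei + lo_j * ej)
            ) / ((hi_i - lo_i) * (hi_j - lo_j))

    asym = np.max(np.abs(H - H.T))
    scale = np.max(np.abs(H))
    if scale > 0 and asym > 1e-3 * scale:  # pragma: no cover - symmetric by build
        warnings.warn(
            f"Hessian asymmetry {asym:.2e} exceeds 1e-3 of scale {scale:.2e}; "
            "finite-difference step may be too large"
        )
    return 0.5 * (H + H.T)


def hessian_least_squares(
    model: ModelSpec,
    theta: ParameterVector,
    data: CalibrationData,
    spec: ObjectiveSpec | None = None,
    fd: FDConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Residual-split Hessian of the weighted least-squares objective.

    Writes H = 2 sum_i w_i [ grad z_i grad z_i^T + (z_i - T(phi_i))
    Hess z_i ] with z = T(y) the (possibly log10-transformed) observables
    and w = 1/sigma^2, computing grad z by central differences and
    Hess z by the same stencils applied to z rather than to G.  The
    Gauss-Newton term is then a product of first differences (accurate to
    ~h^2), and stencil noise only enters multiplied by the residuals --
    one to two orders of magnitude more accurate than double-differencing
    G near a good fit, at a cost of at most 2p(p+1) + 1 model
    simulations.  Exact on observables affine in theta.

    The curvature stencils use the (larger) Hessian step of ``fd``; the
    sensitivities use the first-derivative step.

    Returns ``(H, S)`` so callers can reuse the sensitivity matrix.
    """
    spec = spec or ObjectiveSpec()
    fd = fd or FDConfig()
    p = theta.p
    d = data.d
    w = 1.0 / data.noise_scales**2
    nominal1 = np.maximum(
        fd.relative_step * np.abs(theta.values), fd.absolute_step_floor
    )
    minus1, plus1 = _directional_steps(theta, nominal1)
    nominal2 = np.maximum(
        fd.hessian_relative_step * np.abs(theta.values),
        fd.hessian_absolute_step_floor,
    )
    minus2, plus2 = _directional_steps(theta, nominal2)

    def z_at(delta: np.ndarray) -> np.ndarray:
        return transform(
            simulate_observables(model, theta.with_values(theta.values + delta), data),
            spec,
        )

    z0 = z_at(np.zeros(p))
    r = z0 - transform(data.values, spec)

    # sensitivities at the first-derivative step (2p simulations)
    S = np.empty((p, d))
    for n in range(p):
        e = np.zeros(p)
        e[n] = plus1[n]
        z_hi = z_at(e)
        e[n] = -minus1[n]
        z_lo = z_at(e)
        S[n] = (z_hi - z_lo) / (plus1[n] + minus1[n])

    # curvature of z at the second-derivative step: diagonal three-point
    # (2p simulations), off-diagonal four-corner (2p(p-1) simulations)
    d2z_diag = np.zeros((p, d))
    two_sided = np.minimum(minus2, plus2) >= 0.5 * np.minimum(
        nominal2, (minus2 + plus2) / 2
    )
    for n in range(p):
        # parameters hugging a bound have a degenerate stencil; they are
        # pinned out of the free subspace downstream, so skip them
        if not two_sided[n]:
            continue
        a, b = minus2[n], plus2[n]
        e = np.zeros(p)
        e[n] = b
        z_hi = z_at(e)
        e[n] = -a
        z_lo = z_at(e)
        d2z_diag[n] = 2.0 * (b * z_lo - (a + b) * z0 + a * z_hi) / (a * b * (a + b))

    H = 2.0 * (S * w[None, :]) @ S.T
    H += 2.0 * np.diag(((w * r)[None, :] * d2z_diag).sum(axis=1))
    for i in range(p):
        for j in range(i + 1, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = 1.0
            ej[j] = 1.0
            lo_i, hi_i = -minus2[i], plus2[i]
            lo_j, hi_j = -minus2[j], plus2[j]
            d2z_ij = (
                z_at(hi_i * ei + hi_j * ej)
                - z_at(hi_i * ei + lo_j * ej)
                - z_at(lo_i * ei + hi_j * ej)
                + z_at(lo_i * ei + lo_j * ej)
            ) / ((hi_i - lo_i) * (hi_j - lo_j))
            value = 2.0 * float((w * r) @ d2z_ij)
            H[i, j] += value
            H[j, i] += value
    return H, S


def objective_gradient(
    model: ModelSpec,
    theta: ParameterVector,
    data: CalibrationData,
    spec: ObjectiveSpec | None = None,
    fd: FDConfig | None = None,
) -> np.ndarray:
    """Gradient of G via the sensitivity matrix: 2 S W r (2p simulations)."""
    spec = spec or ObjectiveSpec()
    y = simulate_observables(model, theta, data)
    r = residuals(y, data, spec)
    S = sensitivity_matrix(model, theta, data, fd, spec)
    return 2.0 * S @ (r / data.noise_scales)
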