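"""Seeded synthetic-data generators.

Every data-construction procedure used by the package's experiments lives
here: simulated viral-load baselines with Gaussian noise on the log10
scale, half-normal absolute shifts, log-additive multiplicative noise,
norm-scaled perturbation sequences with ordering constraints, and
appended simulated measurements for experimental-design ranking.  All
generators are pure functions of their inputs and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import CalibrationData
from .model import ModelSpec, simulate_observables
from .parameters import ParameterVector

__all__ = [
    "PerturbationScheme",
    "generate_viral_baseline",
    "generate_model_baseline",
    "perturb_absolute",
    "perturb_log",
    "perturb_norm_scaled",
    "append_simulated_measurement",
]


def generate_model_baseline(
    model: ModelSpec,
    theta: ParameterVector,
    times: np.ndarray,
    conditions: list[str] | str = "control",
    noise_sd: float = 0.0,
    seed: int = 0,
    noise_scale_column: float = 1.0,
    log10_noise: bool = False,
) -> CalibrationData:
    """Simulate observables at ``theta`` and add i.i.d. Gaussian noise.

    With ``log10_noise=True`` the noise is added on the log10 scale of a
    positive observable (values are perturbed multiplicatively by
    ``10**eps``).  ``noise_scale_column`` fills the sigma column of the
    returned table (the objective weighting, fixed and known).
    """
    design = CalibrationData(
        times, np.zeros(len(times)), noise_scale_column, conditions
    )
    y = simulate_observables(model, theta, design)
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sd, size=y.size) if noise_sd > 0 else np.zeros(y.size)
    values = 10.0 ** (np.log10(y) + eps) if log10_noise else y + eps
    return design.with_values(values)


def generate_viral_baseline(
    model: ModelSpec,
    theta: ParameterVector,
    times: np.ndarray,
    sigma2: float = 0.15,
    seed: int = 0,
) -> CalibrationData:
    """Viral-load baseline phi_i = log10 V(t_i; theta) + eps_i.

    eps_i ~ N(0, sigma2) on the log10 scale (the model observable is
    already log10 V).  The sigma column is 1 (fixed known weighting).
    """
    return generate_model_baseline(
        model, theta, np.asarray(times, dtype=float),
        noise_sd=float(np.sqrt(sigma2)), seed=seed,
    )


def perturb_absolute(
    phi0: CalibrationData, h_step: float, seed: int = 0
) -> CalibrationData:
    """phi_i = phi0_i + h_step |eps_i| with eps_i standard normal.

    Every point shifts in the direction of sign(h_step) (half-normal
    magnitudes), emulating systematically higher or lower re-measurements.
    """
    rng = np.random.default_rng(seed)
    shift = h_step * np.abs(rng.standard_normal(phi0.d))
    return phi0.with_values(phi0.values + shift)


def perturb_log(
    phi0: CalibrationData, scale: float = 0.8, seed: int = 0
) -> CalibrationData:
    """log phi_i = log phi0_i + scale * eps_i (multiplicative log-normal noise).

    Requires strictly positive values; output is strictly positive for any
    seed.
    """
    if np.any(phi0.values <= 0):
        raise ValueError("log perturbation requires strictly positive values")
    rng = np.random.default_rng(seed)
    return phi0.with_values(
        phi0.values * np.exp(scale * rng.standard_normal(phi0.d))
    )


def perturb_norm_scaled(
    phi0: CalibrationData,
    j: int,
    h_step: float = 0.07,
    seed: int = 0,
    constraints: tuple[tuple[int, int], ...] = (),
    base_offset: float = 0.05,
    max_retries: int = 1000,
) -> CalibrationData:
    """Perturbation with an exact log10-norm target and ordering constraints.

    Draws a standard-normal vector and rescales it so that

        || log10 phi^j - log10 phi^0 ||_2 = (base_offset + j h_step) || log10 phi^0 ||_2

    holds exactly (to rounding).  ``constraints`` are (smaller_row,
    larger_row) index pairs enforced by seeded redraw of the offending
    components (then rescaling to the exact norm again), bounded by
    ``max_retries``.  The default ``h_step=0.07`` makes j=10 reach a
    75% relative log-norm displacement; the alternative preset 0.65/55
    is also accepted.
    """
    if np.any(phi0.values <= 0):
        raise ValueError("norm-scaled perturbation requires strictly positive values")
    target = (base_offset + j * h_step) * np.linalg.norm(np.log10(phi0.values))
    if target == 0:
        return phi0.with_values(phi0.values.copy())
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(phi0.d)
    for _ in range(max_retries):
        norm = np.linalg.norm(eps)
        if norm == 0:
            eps = rng.standard_normal(phi0.d)
            continue
        delta = eps * (target / norm)
        values = 10.0 ** (np.log10(phi0.values) + delta)
        bad = [
            (small, large)
            for small, large in constraints
            if values[small] > values[large]
        ]
        if not bad:
            return phi0.with_values(values)
        for small, large in bad:  # redraw only the offending components
            eps[small] = rng.standard_normal()
            eps[large] = rng.standard_normal()
    raise RuntimeError(
        f"could not satisfy ordering constraints within {max_retries} redraws"
    )


def append_simulated_measurement(
    model: ModelSpec,
    theta_star: ParameterVector,
    data: CalibrationData,
    time: float,
    condition: str = "control",
    delta_phi: float = 0.0,
    noise_scale: float = 1.0,
) -> tuple[CalibrationData, int]:
    """Append phi_s = y(time; theta*) + delta_phi, keeping time order.

    With ``delta_phi = 0`` the appended point matches the model exactly, so
    the MLE and the objective value are unchanged.  Returns the augmented
    data and the row index of the new measurement.
    """
    probe = CalibrationData([time], [0.0], noise_scale, condition)
    y = simulate_observables(model, theta_star, probe)
    return data.append(time, float(y[0]) + delta_phi, noise_scale, condition)


@dataclass(frozen=True)
class PerturbationScheme:
    """A seeded recipe producing perturbed copies of a baseline data set.

    ``kind`` is one of ``absolute_halfnormal`` (params: h_step),
    ``log_additive`` (params: scale) or ``norm_scaled`` (params: j,
    h_step, base_offset).  Identical (kind, params, seed) give identical
    output; ordering ``constraints`` (smaller_row, larger_row) are
    enforced where supported.
    """

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0
    constraints: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("absolute_halfnormal", "log_additive", "norm_scaled"):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")

    def apply(self, phi0: CalibrationData) -> CalibrationData:
        if self.kind == "absolute_halfnormal":
            return perturb_absolute(phi0, seed=self.seed, **self.params)
        if self.kind == "log_additive":
            return perturb_log(phi0, seed=self.seed, **self.params)
        return perturb_norm_scaled(
            phi0, seed=self.seed, constraints=self.constraints, **self.params
        )
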