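"""Experimental-design quantities derived from the data->parameter Jacobian.

The column k of DPsi maps perturbations of data point k to shifts of the
MLE; its absolute column sum is the per-point sensitivity, the maximum
over columns is the induced matrix 1-norm ||DPsi||_1, and the argmax is
the most informative data point.  Appending an exactly-simulated
measurement leaves the MLE unchanged but augments DPsi, so ranking
candidate measurement times by the predicted parameter shift they would
induce selects measurements that most constrain the parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .continuation import (
    ContinuationState,
    SingularHessianError,
    build_continuation_state,
)
from .data import CalibrationData
from .fd import FDConfig, objective_gradient
from .model import ModelSpec
from .objective import ObjectiveSpec
from .parameters import ParameterVector
from .synthetic import append_simulated_measurement

__all__ = [
    "SensitivityReport",
    "CandidateMeasurement",
    "data_point_sensitivity",
    "most_informative_point",
    "dpsi_norm1",
    "sensitivity_report",
    "rank_candidate_measurements",
    "compare_minima_robustness",
    "bic",
]


def data_point_sensitivity(dpsi: np.ndarray, k: int) -> float:
    """Sensitivity of the MLE to data point k: sum_n |DPsi[n, k]| (0-based k)."""
    dpsi = np.asarray(dpsi, dtype=float)
    if not 0 <= k < dpsi.shape[1]:
        raise IndexError(f"data-row index {k} out of range 0..{dpsi.shape[1] - 1}")
    return float(np.abs(dpsi[:, k]).sum())


def dpsi_norm1(dpsi: np.ndarray) -> float:
    """Induced matrix 1-norm: the largest per-point sensitivity."""
    return float(np.abs(np.asarray(dpsi, dtype=float)).sum(axis=0).max())


def most_informative_point(dpsi: np.ndarray) -> tuple[int, float]:
    """(index, value) of the data point maximising the per-point sensitivity.

    Ties break toward the smallest index (earliest measurement).
    """
    dpsi = np.asarray(dpsi, dtype=float)
    if dpsi.size == 0:
        raise ValueError("DPsi is empty")
    col_sums = np.abs(dpsi).sum(axis=0)
    k = int(np.argmax(col_sums))  # argmax returns the first maximum
    return k, float(col_sums[k])


@dataclass(frozen=True)
class SensitivityReport:
    """Per-data-point MLE sensitivities and predicted parameter shifts."""

    per_point_sensitivity: np.ndarray  # length d, absolute column sums
    dpsi_norm: float  # max over columns = ||DPsi||_1
    most_informative_index: int
    per_parameter_shift: np.ndarray  # p x d, percent relative change per unit dphi
    parameter_names: tuple[str, ...]
    row_labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        """Matrix CSV layout: parameter rows + a column-sum row."""
        frame = pd.DataFrame(
            self.per_parameter_shift, index=list(self.parameter_names),
            columns=self.row_labels,
        )
        frame.loc["column-sum"] = self.per_point_sensitivity
        return frame


def sensitivity_report(
    state: ContinuationState, delta_phi: float = 1.0
) -> SensitivityReport:
    """Summarise DPsi: per-point sensitivities and percent parameter shifts.

    ``per_parameter_shift[n, i]`` is the percent relative change of
    parameter n predicted for a perturbation ``delta_phi`` of data point i.
    """
    sens = np.abs(state.dpsi).sum(axis=0)
    idx, norm = most_informative_point(state.dpsi)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = 100.0 * state.dpsi * delta_phi / state.theta_star.values[:, None]
    return SensitivityReport(
        per_point_sensitivity=sens,
        dpsi_norm=norm,
        most_informative_index=idx,
        per_parameter_shift=rel,
        parameter_names=state.theta_star.names,
        row_labels=state.data.row_labels(),
    )


@dataclass(frozen=True)
class CandidateMeasurement:
    """A proposed additional measurement, simulated at the current MLE."""

    time: float
    condition: str
    simulated_value: float
    perturbation: float  # signed delta_phi applied when ranking


def rank_candidate_measurements(
    model: ModelSpec,
    state: ContinuationState,
    times: list[float],
    condition: str,
    delta_phi: float,
    target_parameter: str | None = None,
    spec: ObjectiveSpec | None = None,
    fd: FDConfig | None = None,
    noise_scale: float = 1.0,
) -> pd.DataFrame:
    """Rank candidate measurement times by how much they would inform the fit.

    For each candidate time: append the exactly-simulated value (which
    leaves the MLE unchanged), rebuild DPsi on the augmented data at the
    unchanged MLE, and predict the parameter shift for perturbations
    +/-``delta_phi`` of the appended point.  Returns one row per
    (candidate, sign) with per-parameter percent shifts (tornado-plot
    data), the augmented ||DPsi||_1, and a rank: by |percent shift| of
    ``target_parameter`` if given, else by the augmented norm.  Ties break
    toward the earliest time, then positive sign.
    """
    spec = spec or ObjectiveSpec()
    fd = fd or FDConfig()
    theta = state.theta_star
    records = []
    for time in times:
        augmented, row = append_simulated_measurement(
            model, theta, state.data, time, condition, 0.0, noise_scale
        )
        aug_state = build_continuation_state(model, theta, augmented, spec, fd)
        simulated_value = float(augmented.values[row])
        for sign in (+1.0, -1.0):
            shift = aug_state.dpsi[:, row] * (sign * delta_phi)
            percent = 100.0 * shift / theta.values
            rec = {
                "time": time,
                "condition": condition,
                "delta_phi": sign * delta_phi,
                "simulated_value": simulated_value,
                "augmented_norm1": dpsi_norm1(aug_state.dpsi),
            }
            rec.update(
                {f"shift_{n}": s for n, s in zip(theta.names, shift)}
            )
            rec.update(
                {f"percent_{n}": pc for n, pc in zip(theta.names, percent)}
            )
            records.append(rec)
    columns = (
        ["time", "condition", "delta_phi", "simulated_value", "augmented_norm1"]
        + [f"shift_{n}" for n in theta.names]
        + [f"percent_{n}" for n in theta.names]
    )
    table = pd.DataFrame.from_records(records, columns=columns)
    if table.empty:
        table["rank"] = pd.Series(dtype=int)
        return table
    if target_parameter is not None:
        if target_parameter not in theta.names:
            raise KeyError(f"unknown parameter {target_parameter!r}")
        score = table[f"percent_{target_parameter}"].abs()
    else:
        score = table["augmented_norm1"]
    order = sorted(
        range(len(table)),
        key=lambda i: (-score.iloc[i], table["time"].iloc[i], -table["delta_phi"].iloc[i]),
    )
    ranks = np.empty(len(table), dtype=int)
    ranks[order] = np.arange(1, len(table) + 1)
    table["rank"] = ranks
    return table.sort_values("rank").reset_index(drop=True)


def compare_minima_robustness(
    model: ModelSpec,
    data: CalibrationData,
    thetas: list[ParameterVector],
    spec: ObjectiveSpec | None = None,
    fd: FDConfig | None = None,
    gradient_tolerance: float = 1e-2,
) -> pd.DataFrame:
    """||DPsi||_1 per candidate minimum: smaller = more robust = preferable.

    Each theta should be a stationary point of the objective on this data
    (checked by a finite-difference gradient; a warning is issued
    otherwise).  Candidates with a numerically singular Hessian are
    flagged but the others are still reported.  The result is invariant to
    candidate order and includes pairwise norm ratios against the first
    unflagged candidate.
    """
    spec = spec or ObjectiveSpec()
    fd = fd or FDConfig()
    rows = []
    for i, theta in enumerate(thetas):
        grad = objective_gradient(model, theta, data, spec, fd)
        # scale-free stationarity measure: gradient in relative coordinates
        scaled = np.abs(grad) * np.maximum(np.abs(theta.values), 1e-8)
        if scaled.max() > gradient_tolerance:
            warnings.warn(
                f"candidate {i} does not look stationary "
                f"(scaled |grad|_inf = {scaled.max():.3g})",
                stacklevel=2,
            )
        try:
            state = build_continuation_state(model, theta, data, spec, fd)
            norm = dpsi_norm1(state.dpsi)
            singular = False
        except SingularHessianError:
            norm = np.nan
            singular = True
        rows.append(
            {
                "candidate": i,
                "norm1": norm,
                "singular_hessian": singular,
                **{f"theta_{n}": v for n, v in theta.as_dict().items()},
            }
        )
    table = pd.DataFrame.from_records(rows)
    finite = table.loc[~table["singular_hessian"], "norm1"]
    reference = finite.iloc[0] if len(finite) else np.nan
    table["ratio_to_first"] = table["norm1"] / reference
    return table


def bic(objective_value: float, p: int, d: int) -> float:
    """Bayesian information criterion consistent with the package objective.

    The objective G is the weighted sum of squares, equal (up to additive
    constants shared by all fits of the same model and data) to minus the
    log-likelihood under the Gaussian noise model with the sigma^2
    exponent convention; so -2 log L = 2 G + const and

        BIC = 2 G + p log d   (constants dropped).

    Only differences within the same model/data are meaningful:
    Delta BIC = 2 Delta G.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    return 2.0 * float(objective_value) + p * float(np.log(d))
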