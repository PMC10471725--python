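"""Linear test model y = X theta with closed-form MLE and data Jacobian.

For observables affine in the parameters the weighted least-squares
problem has the exact solution theta* = (X' W X)^{-1} X' W phi with
W = diag(1/sigma^2), so the data->parameter Jacobian is the constant
matrix (X' W X)^{-1} X' W and the first-order predictor is exact for any
data perturbation.  This makes the linear model the oracle against which
the finite-difference continuation machinery is checked.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

from ..model import ModelSpec
from ..parameters import ParameterVector

__all__ = ["linear_model", "linear_mle", "linear_dpsi"]


def linear_model(X: np.ndarray) -> tuple[ModelSpec, ParameterVector]:
    """Wrap a design matrix as a (degenerate) dynamical model.

    The model carries one constant state; the observable at "time" i is
    row i of X dotted with theta.  Data row times must be 0..d-1 in
    order.  Returns the model and a zero starting parameter vector with
    unbounded Omega.  Raises on rank-deficient X (which would map to a
    singular Hessian).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-d design matrix")
    d, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank-deficient")

    def rhs(x, t, theta, condition):
        return np.zeros_like(x)

    def initial_state(theta, condition):
        return np.zeros(1)

    def observable(states, times, theta, condition):
        idx = np.rint(times).astype(int)
        if np.any(idx < 0) or np.any(idx >= d):
            raise ValueError("linear-model data times must index rows of X")
        return X[idx] @ theta.values

    model = ModelSpec(
        rhs=rhs, initial_state=initial_state, observable=observable, name="linear"
    )
    theta0 = ParameterVector(np.zeros(p), [f"theta_{i}" for i in range(p)])
    return model, theta0


def linear_mle(
    X: np.ndarray, phi: np.ndarray, sigma: np.ndarray | float = 1.0
) -> np.ndarray:
    """Closed-form weighted least-squares solution (X' W X)^{-1} X' W phi."""
    X = np.asarray(X, dtype=float)
    w = 1.0 / np.broadcast_to(np.asarray(sigma, dtype=float), X.shape[0:1]) ** 2
    A = X.T * w @ X
    return scipy.linalg.solve(A, X.T @ (w * np.asarray(phi, dtype=float)), assume_a="pos")


def linear_dpsi(X: np.ndarray, sigma: np.ndarray | float = 1.0) -> np.ndarray:
    """Closed-form data Jacobian (X' W X)^{-1} X' W (p x d)."""
    X = np.asarray(X, dtype=float)
    w = 1.0 / np.broadcast_to(np.asarray(sigma, dtype=float), X.shape[0:1]) ** 2
    A = X.T * w @ X
    return scipy.linalg.solve(A, X.T * w, assume_a="pos")
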