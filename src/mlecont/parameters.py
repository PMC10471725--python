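"""Bounded, named parameter vectors.

A parameter vector lives in the admissible box Omega = [lower, upper] in
R^p.  All continuation machinery carries bounds along with values so that
finite-difference steps and predicted MLEs can be kept inside Omega.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["ParameterVector"]


@dataclass(frozen=True)
class ParameterVector:
    """A point theta in the admissible parameter region Omega subset R^p.

    Parameters
    ----------
    values : array-like of shape (p,)
        Parameter values.
    names : sequence of str
        One label per parameter.
    lower, upper : array-like of shape (p,), optional
        Bounds of the admissible box Omega.  Default: unbounded
        (``-inf``/``+inf``).
    """

    values: np.ndarray
    names: tuple[str, ...]
    lower: np.ndarray = field(default=None)  # type: ignore[assignment]
    upper: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __init__(
        self,
        values: Sequence[float] | np.ndarray,
        names: Sequence[str],
        lower: Sequence[float] | np.ndarray | None = None,
        upper: Sequence[float] | np.ndarray | None = None,
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("values must be a 1-d vector with p >= 1")
        p = values.size
        names = tuple(str(n) for n in names)
        if len(names) != p:
            raise ValueError(f"{len(names)} names for {p} values")
        lower = (
            np.full(p, -np.inf) if lower is None else np.asarray(lower, dtype=float)
        )
        upper = np.full(p, np.inf) if upper is None else np.asarray(upper, dtype=float)
        if lower.shape != (p,) or upper.shape != (p,):
            raise ValueError("bounds must have shape (p,)")
        if np.any(lower > upper):
            raise ValueError("lower bound exceeds upper bound")
        if np.any(values < lower) or np.any(values > upper):
            bad = [
                names[i]
                for i in range(p)
                if values[i] < lower[i] or values[i] > upper[i]
            ]
            raise ValueError(f"parameter(s) outside Omega: {bad}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @property
    def p(self) -> int:
        """Number of parameters."""
        return self.values.size

    def with_values(self, values: np.ndarray, clip: bool = False) -> "ParameterVector":
        """Return a copy holding ``values`` with the same names/bounds.

        With ``clip=True`` values are clipped into Omega first.
        """
        values = np.asarray(values, dtype=float)
        if clip:
            values = np.clip(values, self.lower, self.upper)
        return ParameterVector(values, self.names, self.lower, self.upper)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        pairs = ", ".join(f"{n}={v:.6g}" for n, v in zip(self.names, self.values))
        return f"ParameterVector({pairs})"
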