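"""Calibration data tables.

The data phi against which a dynamical model is calibrated: one row per
measurement, each carrying a time, an observed value, a known noise scale
sigma and an experimental-condition label (e.g. ``"control"`` vs
``"treated"``).  Multiple conditions realise simultaneous fits to several
experiments by flattening into one residual vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["CalibrationData"]

DEFAULT_CONDITION = "control"


@dataclass(frozen=True)
class CalibrationData:
    """Ordered calibration measurements (time, value, sigma, condition).

    Invariants: all fields share length d >= 1, noise scales are strictly
    positive, and times are strictly increasing within each condition.
    """

    times: np.ndarray
    values: np.ndarray
    noise_scales: np.ndarray
    conditions: tuple[str, ...]

    def __init__(
        self,
        times: Sequence[float],
        values: Sequence[float],
        noise_scales: Sequence[float] | float | None = None,
        conditions: Sequence[str] | str | None = None,
    ) -> None:
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        d = times.size
        if d < 1 or times.ndim != 1:
            raise ValueError("times must be a 1-d vector with d >= 1")
        if values.shape != (d,):
            raise ValueError("values must match times in length")
        if noise_scales is None:
            noise_scales = np.ones(d)
        elif np.isscalar(noise_scales):
            noise_scales = np.full(d, float(noise_scales))
        else:
            noise_scales = np.asarray(noise_scales, dtype=float)
        if noise_scales.shape != (d,):
            raise ValueError("noise_scales must match times in length")
        if np.any(noise_scales <= 0):
            raise ValueError("noise scales must be strictly positive")
        if conditions is None:
            conditions = (DEFAULT_CONDITION,) * d
        elif isinstance(conditions, str):
            conditions = (conditions,) * d
        else:
            conditions = tuple(str(c) for c in conditions)
        if len(conditions) != d:
            raise ValueError("conditions must match times in length")
        for cond in dict.fromkeys(conditions):
            t_c = times[np.array([c == cond for c in conditions])]
            if np.any(np.diff(t_c) <= 0):
                raise ValueError(
                    f"times within condition {cond!r} must be strictly increasing"
                )
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "noise_scales", noise_scales)
        object.__setattr__(self, "conditions", conditions)

    @property
    def d(self) -> int:
        """Number of data rows."""
        return self.times.size

    @property
    def condition_order(self) -> tuple[str, ...]:
        """Distinct conditions in first-appearance order."""
        return tuple(dict.fromkeys(self.conditions))

    def rows_for(self, condition: str) -> np.ndarray:
        """Indices of the rows belonging to ``condition``."""
        return np.flatnonzero(np.array([c == condition for c in self.conditions]))

    def with_values(self, values: np.ndarray) -> "CalibrationData":
        """Same design (times/sigma/conditions), new observed values."""
        return CalibrationData(self.times, values, self.noise_scales, self.conditions)

    def append(
        self,
        time: float,
        value: float,
        noise_scale: float = 1.0,
        condition: str = DEFAULT_CONDITION,
    ) -> tuple["CalibrationData", int]:
        """Insert one measurement keeping per-condition time order.

        Returns the augmented table and the row index at which the new
        measurement landed.
        """
        times = np.append(self.times, float(time))
        values = np.append(self.values, float(value))
        sigmas = np.append(self.noise_scales, float(noise_scale))
        conditions = self.conditions + (condition,)
        # stable sort by (condition appearance order, time) keeps unrelated
        # conditions untouched and slots the new row into place
        order_key = {c: i for i, c in enumerate(dict.fromkeys(conditions))}
        order = sorted(
            range(len(times)), key=lambda i: (order_key[conditions[i]], times[i])
        )
        new_index = order.index(len(times) - 1)
        return (
            CalibrationData(
                times[order],
                values[order],
                sigmas[order],
                tuple(conditions[i] for i in order),
            ),
            new_index,
        )

    def row_labels(self) -> list[str]:
        """Human-readable labels ``time@condition`` for reports."""
        return [f"{t:g}@{c}" for t, c in zip(self.times, self.conditions)]

    # ---- pandas / CSV interface -------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "value": self.values,
                "sigma": self.noise_scales,
                "condition": list(self.conditions),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CalibrationData":
        if "time" not in frame or "value" not in frame:
            raise ValueError("calibration table needs 'time' and 'value' columns")
        sigma = frame["sigma"].to_numpy() if "sigma" in frame else None
        cond = list(frame["condition"]) if "condition" in frame else None
        return cls(frame["time"].to_numpy(), frame["value"].to_numpy(), sigma, cond)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CalibrationData":
        return cls.from_frame(pd.read_csv(path))
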