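"""Run configuration: a YAML-serialisable description of one analysis.

A run is reproducible from its config plus seed alone: model selector,
parameter table (name, value, lower, upper), objective kind, FD settings,
solver tolerances and the top-level seed.  All module randomness flows
from the one seed via named streams so repeat runs decompose.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .fd import FDConfig
from .models import get_model
from .model import ModelSpec
from .objective import ObjectiveSpec
from .parameters import ParameterVector

__all__ = ["RunConfig", "seed_stream"]


def seed_stream(seed: int, name: str) -> int:
    """Derive a per-module seed (< 2**31) from the top-level seed."""
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Serializable description of a run."""

    model: str = "viral"
    parameters: list[dict] = field(default_factory=list)
    # each entry: {name, value, lower, upper}
    objective_kind: str = "weighted_sum_of_squares"
    relative_step: float = 1e-4
    absolute_step_floor: float = 1e-8
    hessian_diagonal_scheme: str = "central"
    rtol: float = 1e-10
    atol: float = 1e-12
    seed: int = 0
    model_options: dict = field(default_factory=dict)

    # ---- factories --------------------------------------------------
    def build_model(self) -> tuple[ModelSpec, ParameterVector]:
        model, default_theta = get_model(self.model, **self.model_options)
        model.rtol = self.rtol
        model.atol = self.atol
        if self.parameters:
            theta = ParameterVector(
                [row["value"] for row in self.parameters],
                [row["name"] for row in self.parameters],
                [row.get("lower", -np.inf) for row in self.parameters],
                [row.get("upper", np.inf) for row in self.parameters],
            )
        else:
            theta = default_theta
        return model, theta

    def objective_spec(self) -> ObjectiveSpec:
        return ObjectiveSpec(kind=self.objective_kind)

    def fd_config(self) -> FDConfig:
        return FDConfig(
            relative_step=self.relative_step,
            absolute_step_floor=self.absolute_step_floor,
            hessian_diagonal_scheme=self.hessian_diagonal_scheme,
        )

    # ---- serialisation ----------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def digest(self) -> str:
        """Stable hash of the config for run logs."""
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]
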