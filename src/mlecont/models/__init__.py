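"""Built-in models and the model registry.

``get_model(name)`` resolves the registry keys ``"viral"``, ``"nsclc"``
and ``"linear"``; a custom model is loadable from ``"path/to/module.py:factory"``
where ``factory()`` returns a ``(ModelSpec, ParameterVector)`` pair.
"""

from __future__ import annotations

import importlib.util
from pathlib import Path

import numpy as np

from ..model import ModelSpec
from ..parameters import ParameterVector
from .linear import linear_dpsi, linear_mle, linear_model
from .phenotype import PhenotypeConstants, phenotype_model
from .viral import viral_model

__all__ = [
    "get_model",
    "linear_model",
    "linear_mle",
    "linear_dpsi",
    "viral_model",
    "phenotype_model",
    "PhenotypeConstants",
]


def get_model(name: str, **kwargs) -> tuple[ModelSpec, ParameterVector]:
    """Resolve a registry key or ``module.py:factory`` path to a model."""
    if name == "viral":
        return viral_model(**kwargs)
    if name == "nsclc":
        return phenotype_model(**kwargs)
    if name == "linear":
        X = kwargs.pop("X", np.eye(3))
        return linear_model(X)
    if ":" in name:
        path, attr = name.rsplit(":", 1)
        spec = importlib.util.spec_from_file_location(Path(path).stem, path)
        if spec is None or spec.loader is None:
            raise ValueError(f"cannot load model module from {path!r}")
        module = importlib.util.module_from_spec(spec)
        spec.loader.exec_module(module)
        return getattr(module, attr)(**kwargs)
    raise KeyError(f"unknown model {name!r}; registry has 'viral', 'nsclc', 'linear'")
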