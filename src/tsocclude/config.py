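"""Run configuration: YAML parsing, validation, model plugins, manifests.

Models are supplied as *plugins*: either an importable factory path
(``package.module:factory``, a zero-argument callable returning a
:class:`~tsocclude.core.BlackBoxModel`) or a builtin toy-box shorthand such
as ``echo:0``, ``linear:0.7,0.3``, ``window_gated:0,3,25`` or
``threshold_classifier:0,0.0``.  This keeps the tool model-agnostic —
no framework-specific weight deserialization.

Every run writes a manifest beside its outputs: the resolved configuration,
seed, package version, and the exact number of black-box invocations.
"""

from __future__ import annotations

import importlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional, Union

import numpy as np
import yaml

from .core import BlackBoxModel, SignalTensor
from .occlusion import DATASET_MEAN

__all__ = [
    "RunConfig",
    "ConfigurationError",
    "parse_occlusion_value",
    "resolve_model",
    "CountingModel",
    "write_manifest",
]


class ConfigurationError(ValueError):
    """Invalid or incomplete run configuration."""


_SCHEMA: Dict[str, type] = {
    "data": str,
    "model": str,
    "occlusion_value": (int, float, str),
    "window_size": int,
    "topk": int,
    "n_global": int,
    "threshold": (int, float),
    "quantile": (int, float),
    "tolerance": int,
    "som_rows": int,
    "som_cols": int,
    "som_sigma": (int, float),
    "som_lr": (int, float),
    "som_steps": int,
    "som_topology": str,
    "seed": int,
    "out_dir": str,
    "signals": (list, str),
    "mode": str,
}


@dataclass
class RunConfig:
    """Validated key-value run configuration (all keys optional)."""

    options: Dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config root must be a mapping, got {type(raw).__name__}")
        return cls.validated(raw)

    @classmethod
    def validated(cls, raw: Dict[str, Any]) -> "RunConfig":
        for key, value in raw.items():
            if key not in _SCHEMA:
                raise ConfigurationError(
                    f"unknown config key {key!r}; known keys: {sorted(_SCHEMA)}"
                )
            if not isinstance(value, _SCHEMA[key]):
                raise ConfigurationError(
                    f"config key {key!r} expects {_SCHEMA[key]}, got {type(value).__name__}"
                )
        return cls(options=dict(raw))

    def get(self, key: str, default: Any = None) -> Any:
        return self.options.get(key, default)

    def to_dict(self) -> Dict[str, Any]:
        return dict(self.options)


def parse_occlusion_value(text: Union[str, float]) -> Union[float, str]:
    """Parse ``zero`` / ``mean`` / a float literal into an occlusion value."""
    if isinstance(text, (int, float)):
        return float(text)
    if text == "zero":
        return 0.0
    if text == "mean":
        return DATASET_MEAN
    try:
        return float(text)
    except ValueError:
        raise ConfigurationError(
            f"occlusion value must be 'zero', 'mean' or a number, got {text!r}"
        ) from None


_BUILTIN_BOXES = ("constant", "echo", "linear", "window_gated", "threshold_classifier")


def resolve_model(ref: str) -> BlackBoxModel:
    """Resolve a model plugin reference.

    ``module.path:factory`` imports and calls the factory; a builtin
    shorthand ``kind:arg1,arg2`` builds a synthetic toy box.
    """
    from .synthetic import make_black_box

    kind, _, argtext = ref.partition(":")
    if kind in _BUILTIN_BOXES:
        args = [a for a in argtext.split(",") if a] if argtext else []
        try:
            if kind == "constant":
                return make_black_box("constant", value=float(args[0]) if args else 0.0)
            if kind == "echo":
                return make_black_box("echo", j=int(args[0]))
            if kind == "linear":
                return make_black_box("linear", weights=[float(a) for a in args])
            if kind == "window_gated":
                return make_black_box(
                    "window_gated", j=int(args[0]), window_index=int(args[1]), d=int(args[2])
                )
            if kind == "threshold_classifier":
                return make_black_box("threshold_classifier", j=int(args[0]), tau=float(args[1]))
        except (IndexError, ValueError) as exc:
            raise ConfigurationError(f"bad arguments for builtin model {ref!r}: {exc}") from exc
    if ":" not in ref:
        raise ConfigurationError(
            f"model reference {ref!r} is neither a builtin ({', '.join(_BUILTIN_BOXES)}) "
            "nor an import path 'module:factory'"
        )
    module_name, attr = ref.split(":", 1)
    try:
        module = importlib.import_module(module_name)
    except ImportError as exc:
        raise ConfigurationError(
            f"cannot import model plugin module {module_name!r}: {exc}. "
            "Provide an importable factory returning a BlackBoxModel."
        ) from exc
    try:
        factory = getattr(module, attr)
    except AttributeError:
        raise ConfigurationError(f"module {module_name!r} has no attribute {attr!r}") from None
    model = factory()
    if not isinstance(model, BlackBoxModel):
        raise ConfigurationError(f"factory {ref!r} did not return a BlackBoxModel")
    return model


class CountingModel:
    """Wrap a model, counting black-box invocations and samples predicted."""

    def __init__(self, model: BlackBoxModel):
        self._inner = model
        self.calls = 0
        self.samples = 0
        counting = self

        def predict(X: SignalTensor) -> np.ndarray:
            counting.calls += 1
            counting.samples += X.n_samples
            return model.predict(X)

        self.model = BlackBoxModel(
            task=model.task,
            predict=predict,
            per_sample_loss=model.per_sample_loss,
            name=model.name,
        )


def write_manifest(out_dir, command: str, config: Dict[str, Any],
                   counter: Optional[CountingModel] = None) -> Path:
    from importlib.metadata import version as pkg_version

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        ver = pkg_version("tsocclude")
    except Exception:
        ver = "unknown"
    manifest = {
        "command": command,
        "config": {k: v for k, v in sorted(config.items())},
        "package_version": ver,
    }
    if counter is not None:
        manifest["black_box_calls"] = counter.calls
        manifest["black_box_samples_predicted"] = counter.samples
    path = out_dir / f"{command}_manifest.json"
    with open(path, "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True, default=str)
    return path
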