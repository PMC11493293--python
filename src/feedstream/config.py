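"""Run configuration: YAML schema covering every tunable default.

A :class:`RunConfig` mirrors the per-module configuration objects in nested
sections. :func:`load_config` validates a YAML file against the schema —
every field is typed with a default, unknown keys are rejected by name —
and :func:`dump_config` round-trips the effective configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Any, Optional

import yaml

from .binarize import BinarizationConfig
from .dataio import SplitSpec
from .glcm import GlcmConfig
from .nn.conv1d import Conv1dNetConfig
from .nn.train import TrainConfig

__all__ = ["ConfigError", "RunConfig", "load_config", "dump_config", "config_to_dict"]


class ConfigError(ValueError):
    """Raised for unknown keys or ill-typed values in a run configuration."""


@dataclass(frozen=True)
class DataSection:
    """Synthetic dataset scale: clips per class and clip geometry."""

    n_per_class: int = 20
    n_frames: int = 12
    frame_height: int = 64
    frame_width: int = 64
    fps: float = 24.0


@dataclass(frozen=True)
class FlowSection:
    """Optical-flow solver and rendering parameters."""

    smoothness_weight: float = 15.0
    n_iterations: int = 100
    max_magnitude: float = 8.0  # fixed rendering scale so intensity encodes absolute motion


@dataclass(frozen=True)
class BackboneSection:
    """2-D backbone profile: 'reduced' (desk-scale) or 'full' (canonical)."""

    profile: str = "reduced"

    def __post_init__(self) -> None:
        if self.profile not in ("reduced", "full"):
            raise ConfigError(f"backbone.profile must be 'reduced' or 'full', got {self.profile!r}")


@dataclass(frozen=True)
class FusionSection:
    method: str = "vote"  # 'vote' or 'score_sum'
    averaging: str = "macro"

    def __post_init__(self) -> None:
        if self.method not in ("vote", "score_sum"):
            raise ConfigError(f"fusion.method must be 'vote' or 'score_sum', got {self.method!r}")
        if self.averaging not in ("macro", "micro"):
            raise ConfigError(f"fusion.averaging must be 'macro' or 'micro', got {self.averaging!r}")


@dataclass(frozen=True)
class RunConfig:
    """Top-level configuration of an end-to-end run."""

    seed: int = 7
    data: DataSection = field(default_factory=DataSection)
    split: SplitSpec = field(default_factory=SplitSpec)
    flow: FlowSection = field(default_factory=FlowSection)
    binarization: BinarizationConfig = field(default_factory=BinarizationConfig)
    glcm: GlcmConfig = field(default_factory=GlcmConfig)
    backbone: BackboneSection = field(default_factory=BackboneSection)
    conv1d: Conv1dNetConfig = field(default_factory=Conv1dNetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    fusion: FusionSection = field(default_factory=FusionSection)


def _coerce(value: Any, target_type: Any, path: str) -> Any:
    # tuples arrive from YAML as lists
    origin = getattr(target_type, "__origin__", None)
    if origin is tuple and isinstance(value, (list, tuple)):
        args = target_type.__args__
        if len(args) == 2 and args[1] is Ellipsis:
            return tuple(_coerce(v, args[0], path) for v in value)
        if len(args) == len(value):
            return tuple(_coerce(v, t, path) for v, t in zip(value, args))
        raise ConfigError(f"{path}: expected {len(args)} elements, got {len(value)}")
    if target_type is float and isinstance(value, int) and not isinstance(value, bool):
        return float(value)
    return value


def _build(cls: type, data: dict, path: str = "") -> Any:
    if not isinstance(data, dict):
        raise ConfigError(f"{path or 'config'}: expected a mapping, got {type(data).__name__}")
    known = {f.name: f for f in fields(cls)}
    unknown = [k for k in data if k not in known]
    if unknown:
        loc = f"{path}." if path else ""
        raise ConfigError(f"unknown configuration key(s): {', '.join(loc + k for k in sorted(unknown))}")
    kwargs = {}
    for name, f in known.items():
        if name not in data:
            continue
        sub_path = f"{path}.{name}" if path else name
        ftype = f.type if not isinstance(f.type, str) else _resolve_type(cls, f.name)
        if is_dataclass(ftype):
            kwargs[name] = _build(ftype, data[name], sub_path)
        else:
            kwargs[name] = _coerce(data[name], ftype, sub_path)
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path or 'config'}: {exc}") from exc


def _resolve_type(cls: type, name: str) -> Any:
    import typing

    hints = typing.get_type_hints(cls)
    return hints[name]


def load_config(path: Optional[Path] = None, overrides: Optional[dict] = None) -> RunConfig:
    """Load a YAML run configuration; an empty/missing file yields defaults.

    Unknown keys raise :class:`ConfigError` naming the offending key.
    ``overrides`` (a nested dict) is merged on top of the file contents.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"configuration root must be a mapping, got {type(loaded).__name__}")
        data = loaded
    if overrides:
        data = _merge(data, overrides)
    return _build(RunConfig, data)


def _merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def config_to_dict(config: Any) -> Any:
    """Recursively convert a (nested) config dataclass to plain types."""
    if is_dataclass(config):
        return {f.name: config_to_dict(getattr(config, f.name)) for f in fields(config)}
    if isinstance(config, tuple):
        return [config_to_dict(v) for v in config]
    return config


def dump_config(config: RunConfig, path: Path) -> Path:
    """Write the effective configuration as YAML (round-trips via load)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))
    return path
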