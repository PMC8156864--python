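"""Pipeline configuration: defaults, YAML/JSON loading, overrides, validation."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .detection import ClusterParams, DetectionConfig, HoughParams
from .tracking import TrackerConfig

__all__ = ["PipelineConfig", "load_config", "dump_config"]


@dataclass
class PipelineConfig:
    """Every tunable of the segmentation/detection/tracking/evaluation pipeline."""

    n_background: int = 50  # frames for the temporal-median background
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    dist_max: float = 30.0  # truth-matching radius, px (~half a fish length)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_background < 1:
            raise ValueError("n_background must be >= 1")
        if self.dist_max <= 0:
            raise ValueError("dist_max must be positive")


def _to_dict(obj) -> dict:
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_dict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


_SUBMODELS = {
    "detection": DetectionConfig,
    "tracker": TrackerConfig,
    "hough": HoughParams,
    "cluster": ClusterParams,
}


def _build(cls, data: dict, path: str = ""):
    """Recursively construct a dataclass, rejecting unknown keys."""
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown config keys at {path or 'top level'}: {sorted(unknown)}")
    kwargs = {}
    for name in fields:
        if name not in data:
            continue
        val = data[name]
        if name in _SUBMODELS and isinstance(val, dict):
            kwargs[name] = _build(_SUBMODELS[name], val, f"{path}{name}.")
        elif isinstance(val, list):
            kwargs[name] = tuple(val)
        else:
            kwargs[name] = val
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as e:
        raise ValueError(f"invalid config at {path or 'top level'}: {e}") from e


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load a pipeline config: CLI overrides win over file, file over defaults.

    ``overrides`` uses dotted keys into the nested structure, e.g.
    ``{"tracker.max_age": 3, "detection.sigma_head": 6}``.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = (json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)) or {}
    for key, val in (overrides or {}).items():
        node = data
        parts = key.split(".")
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = val
    return _build(PipelineConfig, data)


def dump_config(cfg: PipelineConfig, path: str | Path | None = None) -> str:
    """Serialise a config to YAML; round-trips through load_config."""
    text = yaml.safe_dump(_to_dict(cfg), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
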