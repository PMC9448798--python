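"""YAML configuration loading with strict key validation.

Every config schema is a frozen dataclass whose defaults are the study
settings, so an empty file yields the default run and unknown keys are
rejected rather than silently ignored.
"""

from __future__ import annotations

from dataclasses import asdict, fields, is_dataclass
from pathlib import Path

import yaml

from .mil import AugmentationConfig, TrainingConfig
from .synthetic import SyntheticCohortSpec

__all__ = [
    "load_training_config",
    "load_cohort_spec",
    "dump_config",
    "config_to_dict",
]


def _build(cls, data: dict, path: str):
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping, got {type(data).__name__}")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(
            f"{path}: unknown key(s) {sorted(unknown)}; valid keys: {sorted(known)}"
        )
    kwargs = {}
    for name, value in data.items():
        f = known[name]
        if f.name == "augmentation":
            value = _build(AugmentationConfig, value, f"{path}.augmentation")
        kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: {exc}") from exc


def _load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return {} if data is None else data


def load_training_config(path: str | Path) -> TrainingConfig:
    """Load a TrainingConfig from YAML; missing keys take study defaults."""
    return _build(TrainingConfig, _load_yaml(path), str(path))


def load_cohort_spec(path: str | Path) -> SyntheticCohortSpec:
    return _build(SyntheticCohortSpec, _load_yaml(path), str(path))


def config_to_dict(config) -> dict:
    if not is_dataclass(config):
        raise TypeError("expected a dataclass config")
    return asdict(config)


def dump_config(config, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)
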