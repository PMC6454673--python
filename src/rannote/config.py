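"""Run configuration: YAML documents, strict key checking, snapshots.

A run config is a single YAML (or JSON) document with per-stage blocks;
unknown keys are rejected with their full key path.  Every CLI run writes a
resolved-config snapshot next to its outputs so results can be reproduced.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .schema import EntityType
from .synthetic import GeneratorConfig, PerturbationConfig
from .model.tagger import TrainConfig


def load_yaml(path: str | Path) -> dict:
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return data


def _check_keys(data: dict, allowed: set[str], prefix: str) -> None:
    unknown = set(data) - allowed
    if unknown:
        key = sorted(unknown)[0]
        path = f"{prefix}.{key}" if prefix else key
        raise ValueError(f"unknown config key: {path}")


def generator_config_from_dict(data: dict, prefix: str = "generator"
                               ) -> GeneratorConfig:
    fields = {f.name for f in dataclasses.fields(GeneratorConfig)}
    _check_keys(data, fields, prefix)
    kwargs = dict(data)
    if "entity_type_weights" in kwargs:
        kwargs["entity_type_weights"] = {
            EntityType(k): float(v)
            for k, v in kwargs["entity_type_weights"].items()
        }
    if "lexicons" in kwargs:
        kwargs["lexicons"] = {
            EntityType(k): list(v) for k, v in kwargs["lexicons"].items()
        }
    if "templates" in kwargs:
        kwargs["templates"] = [tuple(t) for t in kwargs["templates"]]
    return GeneratorConfig(**kwargs)


def perturbation_config_from_dict(data: dict, prefix: str = "perturbation"
                                  ) -> PerturbationConfig:
    fields = {f.name for f in dataclasses.fields(PerturbationConfig)}
    _check_keys(data, fields, prefix)
    kwargs = dict(data)
    if kwargs.get("type_confusion"):
        kwargs["type_confusion"] = {
            EntityType(src): {EntityType(t): float(p) for t, p in row.items()}
            for src, row in kwargs["type_confusion"].items()
        }
    return PerturbationConfig(**kwargs)


def train_config_from_dict(data: dict, prefix: str = "train") -> TrainConfig:
    fields = {f.name for f in dataclasses.fields(TrainConfig)}
    _check_keys(data, fields, prefix)
    return TrainConfig(**data)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    if isinstance(obj, dict):
        return {
            (k.value if isinstance(k, EntityType) else str(k)): _jsonable(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_snapshot(config_obj, out_dir: str | Path, name: str) -> Path:
    """Write the resolved configuration as JSON next to the outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{name}.resolved.json"
    path.write_text(
        json.dumps(_jsonable(config_obj), ensure_ascii=False, indent=2) + "\n",
        encoding="utf-8",
    )
    return path
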