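"""Pipeline configuration: schema, YAML loading, overrides and hashing.

The configuration is a nested, schema-validated block per pipeline stage.
Unknown keys are rejected so typos fail loudly before any stage runs. The
``--set key.sub=value`` override syntax coerces values to the type of the
field being replaced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .synthetic import SyntheticConfig

__all__ = [
    "ConfigError",
    "RadiobioConfig",
    "StatsConfig",
    "MlConfig",
    "PipelineConfig",
    "load_config",
    "config_to_dict",
    "config_hash",
]


class ConfigError(ValueError):
    """Raised on schema violations in a pipeline configuration."""


@dataclass
class RadiobioConfig:
    eud_alpha: float = 0.3
    dose_floor: float = 0.01
    td50: float = 24.5
    m: float = 2.0
    gamma50: float = 2.0
    dref: float = 2.0
    n: float = 1.0
    formula_mode: str = "printed"


@dataclass
class StatsConfig:
    t_variant: str = "pooled"


@dataclass
class MlConfig:
    train_fraction: float = 0.7
    folds: int = 5
    models: tuple = ("MLR", "SVM", "DT", "KNN")
    dt_max_depth: int = 3
    svm_c: float = 1.0
    svm_gamma: str = "scale"
    knn_k: int = 5


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "lungeud_out"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    radiobio: RadiobioConfig = field(default_factory=RadiobioConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    ml: MlConfig = field(default_factory=MlConfig)


def _build_dataclass(cls, data: dict, path: str = ""):
    if not isinstance(data, dict):
        raise ConfigError(f"config block {path or cls.__name__!r} must be a mapping")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(
            f"unknown config key(s) {sorted(unknown)} in block '{path or 'root'}'"
        )
    kwargs = {}
    for name, value in data.items():
        f = known[name]
        if dataclasses.is_dataclass(f.type) or name in (
            "synthetic",
            "radiobio",
            "stats",
            "ml",
        ):
            sub_cls = {
                "synthetic": SyntheticConfig,
                "radiobio": RadiobioConfig,
                "stats": StatsConfig,
                "ml": MlConfig,
            }[name]
            kwargs[name] = _build_dataclass(sub_cls, value, f"{path}{name}.")
        else:
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid config block '{path or 'root'}': {exc}") from exc


def _coerce(current, raw: str):
    if isinstance(current, bool):
        return raw.lower() in ("1", "true", "yes")
    if isinstance(current, int) and not isinstance(current, bool):
        return int(raw)
    if isinstance(current, float):
        return float(raw)
    if isinstance(current, (tuple, list)):
        return tuple(part.strip() for part in raw.split(","))
    return raw


def _apply_override(cfg: PipelineConfig, spec: str) -> None:
    if "=" not in spec:
        raise ConfigError(f"override {spec!r} must have the form key.sub=value")
    dotted, raw = spec.split("=", 1)
    parts = dotted.strip().split(".")
    target = cfg
    for part in parts[:-1]:
        if not hasattr(target, part):
            raise ConfigError(f"unknown config key {dotted!r}")
        target = getattr(target, part)
    leaf = parts[-1]
    if not hasattr(target, leaf):
        raise ConfigError(f"unknown config key {dotted!r}")
    setattr(target, leaf, _coerce(getattr(target, leaf), raw))


def load_config(
    path: str | Path | None = None,
    overrides: tuple = (),
    seed: int | None = None,
    outdir: str | None = None,
) -> PipelineConfig:
    """Load and validate a pipeline configuration.

    ``overrides`` are ``key.sub=value`` strings applied after the file;
    ``seed``/``outdir`` override the global fields and the global seed is
    propagated to the synthetic block.
    """
    if path is None:
        cfg = PipelineConfig()
    else:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = _build_dataclass(PipelineConfig, data)
    for spec in overrides:
        _apply_override(cfg, spec)
    if seed is not None:
        cfg.seed = int(seed)
    if outdir is not None:
        cfg.outdir = str(outdir)
    cfg.synthetic.seed = cfg.seed
    # re-validate nested dataclass invariants after overrides
    try:
        cfg.synthetic.__post_init__()
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    return cfg


def config_to_dict(cfg: PipelineConfig) -> dict:
    return dataclasses.asdict(cfg)


def config_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(config_to_dict(cfg), sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
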