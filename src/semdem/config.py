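"""Run configuration: one object bundling every tunable of the pipeline.

Two named profiles are provided.  ``full`` is the original study design
(13 instances, 3000 trials per word); ``scaled`` keeps the architecture at
full size (12 areas x 625+625 cells — structure is never shrunk) but reduces
training length and replicate count so an experiment runs on a desk machine.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields

import yaml

from .assay import AssayConfig
from .dynamics import DynamicsParams
from .netarch import ArchitectureConfig, ConfigurationError, KernelParams
from .plasticity import PlasticityRule
from .protocol import TrainingSchedule

__all__ = ["RunConfig", "PROFILES", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    profile: str = "scaled"
    architecture: ArchitectureConfig = field(default_factory=ArchitectureConfig)
    dynamics: DynamicsParams = field(default_factory=DynamicsParams)
    plasticity: PlasticityRule = field(default_factory=PlasticityRule)
    schedule: TrainingSchedule = field(default_factory=TrainingSchedule)
    assay: AssayConfig = field(default_factory=AssayConfig)
    n_instances: int = 13
    n_object_words: int = 6
    n_action_words: int = 6
    k_active: int = 19
    severities: tuple[int, ...] = (0, 30, 60, 90)
    lesion_types: tuple[str, ...] = ("GM", "WM")
    lesion_target: str = "AT"

    def validate(self) -> None:
        if self.k_active > self.architecture.grid_rows * self.architecture.grid_cols:
            raise ConfigurationError("k_active exceeds the number of grid cells")
        if self.n_instances < 1:
            raise ConfigurationError("need at least one instance")
        for lt in self.lesion_types:
            if lt not in ("GM", "WM"):
                raise ConfigurationError(f"unknown lesion type {lt!r}")


def _scaled() -> RunConfig:
    return RunConfig(
        profile="scaled",
        schedule=TrainingSchedule(trials_per_word=300),
        n_instances=5,
    )


def _full() -> RunConfig:
    return RunConfig(profile="full",
                     schedule=TrainingSchedule(trials_per_word=3000),
                     n_instances=13)


PROFILES = {"scaled": _scaled, "full": _full}


def _to_dict(obj) -> dict:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_dict(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


_NESTED = {
    "architecture": ArchitectureConfig, "dynamics": DynamicsParams,
    "plasticity": PlasticityRule, "schedule": TrainingSchedule, "assay": AssayConfig,
}


def _from_dict(cls, d: dict):
    kwargs = {}
    names = {f.name for f in fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ConfigurationError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    for f in fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        if f.name in _NESTED and isinstance(v, dict):
            v = _from_dict(_NESTED[f.name], v)
        elif f.name in ("within_kernel", "between_kernel") and isinstance(v, dict):
            v = _from_dict(KernelParams, v)
        elif isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML; a ``profile`` key selects the base profile
    and the remaining keys override its fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    base = raw.pop("profile", "scaled")
    if base not in PROFILES:
        raise ConfigurationError(f"unknown profile {base!r}")
    cfg = PROFILES[base]()
    merged = _to_dict(cfg)

    def deep_merge(dst: dict, src: dict) -> dict:
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                deep_merge(dst[k], v)
            else:
                dst[k] = v
        return dst

    deep_merge(merged, raw)
    merged["profile"] = base
    cfg = _from_dict(RunConfig, merged)
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_dict(cfg), fh, sort_keys=False)
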