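"""Run configuration: nested YAML (or JSON) with full defaults.

Every field has a default so a run needs no config file at all; unknown keys
are rejected before any compute.  CLI flags override config keys.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Any, Optional

import yaml

from .encoder import AugmentationSpec, EncoderConfig
from .fusion import FusionConfig
from .models import ClassifierSpec, HeadSpec
from .radiomics import RadiomicsConfig
from .synthetic import CohortConfig, sbrt_preset, surgery_preset

__all__ = ["RunConfig", "load_config"]


@dataclass
class SchemeConfig:
    """Validation scheme settings."""

    scheme: str = "mcrv"  # "loocv" | "mcrv"
    n_folds: int = 100
    train_frac: float = 0.7
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.scheme not in ("loocv", "mcrv"):
            raise ValueError(f"unknown scheme {self.scheme!r}")


@dataclass
class SynthConfig:
    """Synthetic-cohort section: a preset plus planted-effect knobs."""

    preset: str = "surgery"
    effect_mean_hu: float = 0.0
    effect_texture: float = 1.0
    n_subjects: Optional[int] = None
    n_events: Optional[int] = None
    grid: Optional[int] = None

    def to_cohort_config(self, seed: int) -> CohortConfig:
        make = {"surgery": surgery_preset, "sbrt": sbrt_preset}.get(self.preset)
        if make is None:
            raise ValueError(f"unknown preset {self.preset!r}")
        overrides: dict[str, Any] = {}
        if self.n_subjects is not None:
            overrides["n_subjects"] = self.n_subjects
        if self.n_events is not None:
            overrides["n_events"] = self.n_events
        if self.grid is not None:
            overrides["grid_shape"] = (self.grid,) * 3
        return make(
            seed=seed,
            effect_mean_hu=self.effect_mean_hu,
            effect_texture=self.effect_texture,
            **overrides,
        )


@dataclass
class RunConfig:
    """Top-level configuration for the end-to-end pipeline."""

    seed: int = 0
    out_dir: str = "mfcrad_run"
    variants: tuple[str, ...] = ("PI", "R", "DL", "MFC")
    classifiers: tuple[str, ...] = ("logistic", "svm-rbf", "random-forest")
    synth: SynthConfig = field(default_factory=SynthConfig)
    radiomics: RadiomicsConfig = field(default_factory=RadiomicsConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    augmentation: AugmentationSpec = field(default_factory=AugmentationSpec)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    head: HeadSpec = field(default_factory=HeadSpec)
    scheme: SchemeConfig = field(default_factory=SchemeConfig)


def _build(cls, data: dict, path: str) -> Any:
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config key(s) at {path}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = known[name].type
        default = known[name].default_factory() if known[name].default_factory is not dataclasses.MISSING else None
        if isinstance(value, dict) and default is not None and is_dataclass(default):
            kwargs[name] = _build(type(default), value, f"{path}.{name}")
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a RunConfig from YAML/JSON, applying flat overrides last.

    Unknown keys anywhere in the file raise before any compute.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} must be a mapping")
        data = loaded
    if overrides:
        for key, value in overrides.items():
            if value is None:
                continue
            node = data
            *parents, leaf = key.split(".")
            for p in parents:
                node = node.setdefault(p, {})
            node[leaf] = value
    return _build(RunConfig, data, "run")


def dump_config(config: RunConfig, path: str | Path) -> Path:
    """Write the fully resolved configuration (for the run log)."""
    path = Path(path)
    path.write_text(yaml.safe_dump(dataclasses.asdict(config), sort_keys=False))
    return path
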