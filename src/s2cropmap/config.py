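"""Run configuration: one YAML-serializable object holding every tunable.

Defaults reproduce the published processing settings (10-day grid over DOY
90-300, SG window 7/order 3, RF with 100 trees and min leaf 10, top-50 MDI
selection cut at correlation-cluster height 1, 0.1 ha despeckling with a
100 m majority radius, cloud-score threshold 0.2).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .classify import RFConfig
from .temporal import SmoothingConfig


@dataclass
class SceneConfig:
    rows: int = 60
    cols: int = 60
    class_mix: tuple = (0.25, 0.30, 0.25, 0.20)
    patch: int = 5
    zone: str = "SJ"


@dataclass
class SelectionConfig:
    top_k: int = 50
    threshold: float = 1.0
    method: str = "ward"
    criterion: str = "distance"


@dataclass
class DespeckleConfig:
    enabled: bool = True
    min_area_ha: float = 0.1
    radius_m: float = 100.0
    pixel_size_m: float = 10.0

    @property
    def min_pixels(self) -> int:
        # strict "< 0.1 ha": at 10 m pixels a 10-pixel (0.1 ha) patch survives
        return int(round(self.min_area_ha * 10000 / self.pixel_size_m ** 2))

    @property
    def radius_px(self) -> int:
        return int(round(self.radius_m / self.pixel_size_m))


@dataclass
class RunConfig:
    seed: int = 0
    cloud_threshold: float = 0.2
    zones: tuple = ("SJ",)
    scene: SceneConfig = field(default_factory=SceneConfig)
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    rf: RFConfig = field(default_factory=RFConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    despeckle: DespeckleConfig = field(default_factory=DespeckleConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _coerce(cls, data: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for k, v in data.items():
        if k not in fields:
            raise ValueError(f"unknown config key {k!r} for {cls.__name__}")
        if isinstance(v, dict):
            sub = {"scene": SceneConfig, "smoothing": SmoothingConfig,
                   "rf": RFConfig, "selection": SelectionConfig,
                   "despeckle": DespeckleConfig}[k]
            v = _coerce(sub, v)
        elif isinstance(v, list):
            v = tuple(v)
        kwargs[k] = v
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _coerce(RunConfig, data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(clean(cfg.to_dict()), fh, sort_keys=False)
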