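"""Pipeline configuration: one YAML file with per-stage sections.

Every threshold has a documented default; the config round-trips through
serialization losslessly, and command-line flags override file values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .catalog import DEFAULT_FRAME_CM, DEFAULT_PATTERN, HAIR_DPI_THRESHOLD
from .hairs import HairParams
from .lifespan import LIVE_MIN_BRIGHTNESS, TORTUOSITY_THRESHOLD
from .synthetic import RenderConfig, RootSystemParams

__all__ = ["PipelineConfig", "SegmentationConfig", "LifespanConfig",
           "TraitConfig", "SimulateConfig", "load_config", "save_config"]


@dataclass
class SegmentationConfig:
    method: str = "threshold"  # threshold | model
    model_path: str | None = None
    threshold: float = 0.5
    # classical baseline parameters
    flatten_size: int = 35
    block_size: int = 51
    offset: float = 20.0
    opening_radius: int = 1
    min_area: int = 30

    def __post_init__(self) -> None:
        if self.method not in ("threshold", "model"):
            raise ValueError(f"unknown segmentation method {self.method!r}")


@dataclass
class TraitConfig:
    prune_len_mm: float = 1.0
    dof_cm: float = 0.25  # imaged depth of soil


@dataclass
class LifespanConfig:
    min_area: int = 15
    live_min_brightness: float = LIVE_MIN_BRIGHTNESS
    tortuosity_threshold: float = TORTUOSITY_THRESHOLD
    max_shift: int = 20
    roi_min_area: int = 60  # smallest final-frame component that becomes a subject
    roi_margin_px: int = 3


@dataclass
class SimulateConfig:
    growth: RootSystemParams = field(default_factory=RootSystemParams)
    render: RenderConfig = field(default_factory=RenderConfig)
    first_day: int = 1
    pot_id: str = "pot01"

    def days(self) -> list[int]:
        return list(range(self.first_day, self.growth.horizon_days + 1))


@dataclass
class PipelineConfig:
    input_dir: str = "frames"
    output_dir: str = "out"
    naming_pattern: str = DEFAULT_PATTERN
    pot_id: str | None = None
    dpi: int | None = None
    hair_dpi_threshold: int = HAIR_DPI_THRESHOLD
    frame_width_cm: float = DEFAULT_FRAME_CM[0]
    frame_height_cm: float = DEFAULT_FRAME_CM[1]
    seed: int = 0
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    traits: TraitConfig = field(default_factory=TraitConfig)
    hairs: HairParams = field(default_factory=HairParams)
    lifespan: LifespanConfig = field(default_factory=LifespanConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)


_TUPLE_FIELDS = {"hair_length_range_mm", "soil_tint", "live_tint", "senescent_tint"}


def _from_dict(cls, data: dict):
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, dict) and f.default_factory is not dataclasses.MISSING:
            # nested dataclass section
            v = _from_dict(type(f.default_factory()), v)
        elif f.name in _TUPLE_FIELDS and isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def to_dict(config) -> dict:
    return dataclasses.asdict(config)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _from_dict(PipelineConfig, data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(config), fh, sort_keys=True)
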