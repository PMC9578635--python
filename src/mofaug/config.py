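"""Run configuration: a validated, YAML-loadable description of a full
augmentation run.  Unknown keys are rejected so typos fail fast."""

from __future__ import annotations

import math
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .types import PlacementConstraints, TransformRanges, WindowSpec

__all__ = [
    "WindowConfig",
    "ConstraintsConfig",
    "TransformConfig",
    "AugmentationConfig",
    "WeightingConfig",
    "SplitConfig",
    "PhantomConfig",
    "RunConfig",
    "load_config",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class WindowConfig(_Strict):
    """HU window; presets: 'lung' = (-1000, 250), 'liver' = (-100, 250)."""

    preset: Optional[Literal["lung", "liver"]] = "lung"
    lower: Optional[float] = None
    upper: Optional[float] = None

    def to_window(self) -> WindowSpec:
        if self.lower is not None or self.upper is not None:
            if self.lower is None or self.upper is None:
                raise ValueError("both lower and upper must be given")
            return WindowSpec(self.lower, self.upper)
        return WindowSpec(-1000, 250) if self.preset == "lung" else WindowSpec(-100, 250)


class ConstraintsConfig(_Strict):
    border_margin: int = 5
    require_no_overlap: bool = True
    containment_mode: Literal["full_footprint", "anchor_only"] = "full_footprint"
    min_separation: int = 1

    def to_constraints(self) -> PlacementConstraints:
        return PlacementConstraints(
            border_margin=self.border_margin,
            require_no_overlap=self.require_no_overlap,
            containment_mode=self.containment_mode,
            min_separation=self.min_separation,
        )


class TransformConfig(_Strict):
    theta_min: float = 0.0
    theta_max: float = math.pi
    omega_min: float = 0.5
    omega_max: float = 2.0
    mirror_probability: float = 1.0

    def to_ranges(self) -> TransformRanges:
        return TransformRanges(
            theta_range=(self.theta_min, self.theta_max),
            omega_range=(self.omega_min, self.omega_max),
            mirror_probability=self.mirror_probability,
        )


class AugmentationConfig(_Strict):
    mode: Literal["plain", "mof"] = "mof"
    m: int = Field(default=4, ge=0)
    retry_budget: int = Field(default=100, ge=1)
    constraints: ConstraintsConfig = ConstraintsConfig()
    transforms: TransformConfig = TransformConfig()


class WeightingConfig(_Strict):
    eps: float = Field(default=1e-7, gt=0, lt=0.5)


class SplitConfig(_Strict):
    train_fraction: float = Field(default=0.8, gt=0, lt=1)


class PhantomConfig(_Strict):
    """Built-in phantom corpus used when no input directory is given."""

    n_images: int = Field(default=10, ge=1)
    image_size: int = Field(default=512, ge=16)
    n_lesions: int = Field(default=3, ge=0)
    radius_min: float = Field(default=3.0, ge=1.0)
    radius_max: float = Field(default=20.0, ge=1.0)
    noise_sd: float = Field(default=5.0, ge=0.0)


class RunConfig(_Strict):
    """Full pipeline configuration.

    ``input_dir`` points at a corpus manifest (as written by
    ``generate_corpus``); when null, a phantom corpus per ``phantom``
    is generated first.  ``resize_order`` documents that cropping runs
    before resizing.
    """

    seed: int = 0
    input_dir: Optional[str] = None
    output_dir: str = "mofaug_out"
    out_size: int = Field(default=512, ge=16)
    resize_order: Literal["crop_then_resize"] = "crop_then_resize"
    format: Literal["png", "tif", "tiff", "nii", "mhd"] = "png"
    window: WindowConfig = WindowConfig()
    augmentation: AugmentationConfig = AugmentationConfig()
    weighting: WeightingConfig = WeightingConfig()
    split: SplitConfig = SplitConfig()
    phantom: PhantomConfig = PhantomConfig()

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        self.window.to_window()  # validates lower < upper
        return self


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML config file and apply keyword overrides on top."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError("config file must hold a mapping")
            data = loaded
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)
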