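"""Run configuration: validated parameter blocks per pipeline stage.

A :class:`RunConfig` is loadable from YAML; unknown keys are rejected
and physical quantities must be positive.  Defaults reflect the study
conditions the package emulates: 63x confocal imaging of yeast nuclei
(pixel size 0.05 um, z-step 0.4 um), 3 s FRAP sampling over 270 s with
three pre-bleach frames, and MTAC with a 30 kb local band.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["RunConfig", "load_config", "dump_config", "config_hash"]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SegmentationConfig(_Block):
    min_area: int = Field(100, gt=0)
    max_area: Optional[float] = Field(None, gt=0)
    smoothing_sigma: float = Field(2.0, gt=0)
    split_touching: bool = False


class DotConfig(_Block):
    smoothing_sigma: float = Field(1.0, gt=0)
    min_prominence: float = Field(0.5, ge=0)
    # 20 px at 0.05 um/px spans ~2 um around the dot
    window_halfwidth: int = Field(20, gt=0)
    mode: Literal["same_z", "mip"] = "mip"


class FrapConfig(_Block):
    dt: float = Field(3.0, gt=0)
    n_prebleach: int = Field(3, ge=1)
    min_recovery: float = Field(2.0, ge=0)


class MtacConfig(_Block):
    q_threshold: float = Field(0.05, gt=0, le=1)
    local_threshold: int = Field(30_000, gt=0)
    alpha_min: float = Field(0.01, ge=0)


class SimulateConfig(_Block):
    image_size: int = Field(128, gt=0)
    nucleus_radius: float = Field(24.0, gt=0)
    total_intensity: float = Field(200_000.0, ge=0)
    puncta_count: int = Field(4, ge=0)
    puncta_fraction: float = Field(0.5, ge=0, le=1)
    psf_sigma: float = Field(2.0, gt=0)
    background_rate: float = Field(2.0, ge=0)
    read_noise_sd: float = Field(1.0, ge=0)


class RunConfig(_Block):
    pixel_size: float = Field(0.05, gt=0)  # micrometres / pixel
    z_step: float = Field(0.4, gt=0)  # micrometres
    seed: int = Field(0, ge=0)
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    dot: DotConfig = Field(default_factory=DotConfig)
    frap: FrapConfig = Field(default_factory=FrapConfig)
    mtac: MtacConfig = Field(default_factory=MtacConfig)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config; an empty file gives all defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    return RunConfig(**data)


def dump_config(config: RunConfig) -> str:
    """Canonical (sorted-key) YAML form of a config."""
    return yaml.safe_dump(config.model_dump(), sort_keys=True)


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(dump_config(config).encode()).hexdigest()
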