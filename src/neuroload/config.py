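"""Validated pipeline configuration (versioned schema, YAML-loadable)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional, Sequence

import yaml
from pydantic import BaseModel, Field, field_validator

from .montage import ACTICAP_32

CONFIG_SCHEMA_VERSION = 1


class SimulationSettings(BaseModel):
    participants: int = Field(1, ge=1)
    modes: tuple[str, ...] = ("Auditory", "Numeric", "Spatial")
    levels: tuple[int, ...] = (1, 2, 3)
    blocks_per_cell: int = Field(1, ge=1)
    trials_per_block: int = Field(100, ge=1)

    @field_validator("levels")
    @classmethod
    def _levels_valid(cls, v):
        bad = [x for x in v if x not in (1, 2, 3)]
        if bad:
            raise ValueError(f"levels must be drawn from {{1, 2, 3}}, got {bad}")
        return v


class RelevanceRuleSettings(BaseModel):
    channels: tuple[str, ...]
    bands: tuple[str, ...]
    slope: float
    modes: Optional[tuple[str, ...]] = None


class SynthesisSettings(BaseModel):
    channel_names: tuple[str, ...] = ACTICAP_32
    noise_sd: float = Field(0.25, gt=0)
    noise_floor_sd: float = Field(0.3, ge=0)
    relevance: Optional[tuple[RelevanceRuleSettings, ...]] = None  # None = default


class CVSettings(BaseModel):
    k: int = Field(5, ge=2)
    buffer: int = Field(5, ge=0)


class GPRSettings(BaseModel):
    init_length_scale: float = Field(10.0, gt=0)
    init_signal_variance: float = Field(1.0, gt=0)
    init_noise_variance: float = Field(1.0, gt=0)
    max_function_evals: int = Field(100, ge=1)


class PipelineConfig(BaseModel):
    """Everything needed to run simulate -> synthesize -> extract -> evaluate."""

    schema_version: int = CONFIG_SCHEMA_VERSION
    seed: int = 0
    simulation: SimulationSettings = SimulationSettings()
    synthesis: SynthesisSettings = SynthesisSettings()
    cv: CVSettings = CVSettings()
    gpr: GPRSettings = GPRSettings()
    label: Literal["level", "subjective"] = "level"
    methods: tuple[Literal["gpr", "mlr"], ...] = ("gpr", "mlr")

    @field_validator("schema_version")
    @classmethod
    def _schema_supported(cls, v):
        if v != CONFIG_SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {v}")
        return v

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))
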