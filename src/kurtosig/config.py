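"""Pipeline configuration: strict YAML schema, validation, stable hashing."""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["PipelineConfig", "load_config", "save_config", "config_hash"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class PhantomConfig(_Strict):
    grid_shape: Tuple[int, int, int] = (64, 64, 24)
    voxel_size: Tuple[float, float, float] = (2.0, 2.0, 5.0)
    anat_voxel_size: Tuple[float, float, float] = (1.0, 1.0, 3.0)
    snr: float = Field(40.0, gt=0.0)
    noiseless: bool = False


class FitConfig(_Strict):
    sigma: float = Field(1.25, ge=0.0)
    k_max: float = Field(3.0, gt=0.0)
    d_max: float = Field(5.0, gt=0.0)


class HistogramConfig(_Strict):
    md_max: float = Field(3.5, gt=0.0)
    md_step: float = Field(0.05, gt=0.0)
    mk_max: float = Field(3.0, gt=0.0)
    mk_step: float = Field(0.02, gt=0.0)


class SignatureConfig(_Strict):
    tau: float = Field(1e-5, ge=0.0)
    dilate: int = Field(1, ge=0)
    min_cluster: int = Field(10, ge=0)
    md_bounds: Tuple[float, float] = (0.2, 3.0)
    mk_bounds: Tuple[float, float] = (0.1, 2.0)

    @model_validator(mode="after")
    def _ordered(self):
        for lo, hi in (self.md_bounds, self.mk_bounds):
            if lo >= hi:
                raise ValueError("bounds must satisfy lo < hi")
        return self


class EvaluationConfig(_Strict):
    grid: str = Field("anat", pattern="^(anat|dki)$")


class PipelineConfig(_Strict):
    """Full end-to-end pipeline configuration (phantom mode)."""

    seed: int = 0
    n_reference: int = Field(3, ge=1)
    subgroup_label: str = "synthetic"
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    fit: FitConfig = Field(default_factory=FitConfig)
    histogram: HistogramConfig = Field(default_factory=HistogramConfig)
    signature: SignatureConfig = Field(default_factory=SignatureConfig)
    evaluation: EvaluationConfig = Field(default_factory=EvaluationConfig)
    out_dir: Optional[str] = None


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)


def save_config(path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=True)


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash of the canonical JSON form."""
    canon = json.dumps(config.model_dump(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
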