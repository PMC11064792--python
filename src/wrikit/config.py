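"""Run configuration: every tunable default in one validated, hashable object."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["RunConfig", "PreprocessConfig", "MetricsConfig", "ClassifyConfig", "SimulateConfig"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PreprocessConfig(_Strict):
    cutoff_hz: float = Field(10.0, gt=0)
    order: int = Field(2, ge=1)
    kalman_q: float | None = None  # None -> 1e-2 * channel variance
    kalman_r: float | None = None  # None -> estimated from second differences


class MetricsConfig(_Strict):
    prominence_deg: float = Field(10.0, gt=0)
    min_gap_s: float = Field(0.15, gt=0)
    trt_window_s: float = Field(0.5, gt=0)
    trt_threshold_floor_dps: float = Field(15.0, ge=0)
    trt_threshold_frac: float = Field(0.2, ge=0)
    trt_gap_tol_s: float = Field(0.5, ge=0)
    wrist_policy: str = "right"  # or "max"


class ClassifyConfig(_Strict):
    test_frac: float = Field(0.1, gt=0, lt=1)
    n_repeats_cv: int = Field(3, ge=1)
    n_repeat_splits: int = Field(20, ge=0)


class SimulateConfig(_Strict):
    n_per_cell: int | None = None  # None -> the study's demographic cell counts


class RunConfig(_Strict):
    """Top-level pipeline configuration; unknown keys are rejected."""

    version: int = 1
    seed: int = 0
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    metrics: MetricsConfig = Field(default_factory=MetricsConfig)
    classify: ClassifyConfig = Field(default_factory=ClassifyConfig)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))

    def content_hash(self) -> str:
        """Stable short hash of the full configuration (embedded in outputs)."""
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
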