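"""Pipeline configuration."""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator


class DiscretizationSettings(BaseModel):
    method: Literal["fixed_bin_size", "fixed_bin_number"] = "fixed_bin_size"
    bin_width: float = Field(0.1, gt=0)
    n_bins: int = Field(16, ge=2)
    min_policy: Literal["roi_min", "fixed_value"] = "roi_min"
    fixed_min: float = 0.0


class Seeds(BaseModel):
    cohort: int = 0
    splits: int = 1
    forest: int = 2


class PipelineConfig(BaseModel):
    """Everything needed for one end-to-end run, recorded in every output."""

    mode: Literal["synthetic", "real"] = "synthetic"
    cohort_spec_path: Optional[str] = None  # YAML CohortSpec (synthetic mode)
    cohort_csv: Optional[str] = None  # cohort table with file paths (real mode)
    discretization: DiscretizationSettings = DiscretizationSettings()
    min_voxels: int = Field(64, ge=1)
    redundancy_threshold: float = Field(0.85, gt=0, le=1)
    strict_redundancy: bool = True
    n_folds: int = Field(100, ge=1)
    k: int = Field(6, ge=1)
    occurrence_threshold: float = Field(0.90, ge=0, le=1)
    strict_occurrence: bool = True
    alpha: float = Field(0.05, gt=0, lt=1)
    bonferroni_policy: Literal["auto", "fixed"] = "auto"
    bonferroni_m: Optional[int] = Field(None, ge=1)
    summary_features: list[str] = ["ih.cov", "stat.skew"]
    seeds: Seeds = Seeds()
    out_dir: Optional[str] = None
    overwrite: bool = False

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        if self.mode == "real" and not self.cohort_csv:
            raise ValueError("real mode requires cohort_csv")
        if self.bonferroni_policy == "fixed" and self.bonferroni_m is None:
            raise ValueError("bonferroni_policy='fixed' requires bonferroni_m")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))
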