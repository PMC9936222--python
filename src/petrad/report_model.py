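"""Machine-readable report schema.

The JSON report bundle written by the pipeline validates against the
models below; ``data/report_schema.json`` is the JSON-Schema export of
``Report`` shipped with the package.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Optional

from pydantic import BaseModel

from .config import PipelineConfig


class BonferroniInfo(BaseModel):
    m: int
    alpha: float
    threshold: float
    displayed: float


class ReductionInfo(BaseModel):
    threshold: float
    clusters: list[list[str]]
    representatives: list[str]
    retained: list[str]
    dropped_constant: list[str]


class FoldScore(BaseModel):
    fold: int
    dataset: str
    labeling: str
    borderline: float
    outlier: float


class FeatureTest(BaseModel):
    feature: str
    occurrence: float
    U: float
    p: float
    significant: bool


class RankingInfo(BaseModel):
    dataset: str
    labeling: str
    mc_selected_features: int
    occurrence: dict[str, float]
    high_ranking: list[str]
    tests: list[FeatureTest]


class SubgroupCell(BaseModel):
    sex: str
    idh: str
    dataset: str
    feature: str
    n: int
    mean: Optional[float]
    sd: Optional[float]


class Report(BaseModel):
    config: PipelineConfig
    n_patients: int
    exclusions: list[dict]
    bonferroni: BonferroniInfo
    reduction: dict[str, ReductionInfo]
    split_plans: dict[str, list[list[str]]]
    fold_scores: list[FoldScore]
    rankings: list[RankingInfo]
    subgroups: list[SubgroupCell]
    stages: list[str]


def validate_report(doc: dict) -> Report:
    """Validate a report dictionary; raises on schema violations."""
    return Report.model_validate(doc)


def published_schema() -> dict:
    """The JSON-Schema shipped with the package."""
    ref = resources.files("petrad.data").joinpath("report_schema.json")
    return json.loads(ref.read_text())
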