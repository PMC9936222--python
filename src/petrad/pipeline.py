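"""End-to-end orchestration and report generation.

Stage order: cohort load/generation -> eligibility filter -> SUV
extraction -> TBR normalization + extraction -> per-dataset redundancy
reduction -> aligned Monte-Carlo splits (sex and IDH labelings) ->
per-fold borderline/outlier scores -> per-labeling occurrence ranking
with Mann-Whitney / Bonferroni confirmation -> subgroup summaries ->
tables, figures and a machine-readable JSON report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import io as pio
from .config import PipelineConfig
from .features import DiscretizationConfig, extract_all
from .ranking import RankingResult, bonferroni_threshold, rank_features, subgroup_summary
from .redundancy import ReductionReport, reduce_redundancy
from .report_model import validate_report
from .resampling import make_mc_splits, score_folds
from .synthetic import CohortSpec, build_default_cohort_spec, generate_cohort

logger = logging.getLogger("petrad")

__all__ = ["PipelineResult", "run_pipeline", "write_reports"]


@dataclass
class PipelineResult:
    config: PipelineConfig
    cases: list[pio.Case]
    exclusions: pd.DataFrame
    feature_tables: dict[str, pd.DataFrame]  # full 154-column tables per dataset
    reduced_tables: dict[str, pd.DataFrame]
    reduction_reports: dict[str, ReductionReport]
    bonferroni_m: int
    split_plans: dict[str, object]  # labeling -> SplitPlan
    fold_scores: pd.DataFrame
    rankings: list[RankingResult]
    subgroups: pd.DataFrame
    stage_log: list[dict] = field(default_factory=list)


def _load_real_cohort(config: PipelineConfig) -> list[pio.Case]:
    table = pd.read_csv(config.cohort_csv)
    base = Path(config.cohort_csv).parent
    cases = []
    for _, row in table.iterrows():
        volume, lesion, background = pio.load_case(
            base / row["volume_path"],
            base / row["lesion_mask_path"],
            base / row["background_mask_path"],
        )
        record = pio.PatientRecord(
            str(row["patient_id"]), row["sex"], row["idh"],
            str(row["grade"]) if "grade" in row and pd.notna(row["grade"]) else None,
        )
        cases.append(pio.Case(record, volume, lesion, background))
    return cases


def _extract_tables(
    cases: list[pio.Case], disc: DiscretizationConfig
) -> dict[str, pd.DataFrame]:
    rows: dict[str, dict[str, dict[str, float]]] = {"SUV": {}, "TBR": {}}
    for case in cases:
        pid = case.record.patient_id
        bg_mean, _ = pio.background_stats(case.volume, case.background)
        rows["SUV"][pid] = dict(extract_all(case.volume, case.lesion, disc, "SUV"))
        tbr_volume = case.volume.scaled(1.0 / bg_mean)
        rows["TBR"][pid] = dict(extract_all(tbr_volume, case.lesion, disc, "TBR"))
    return {tag: pd.DataFrame.from_dict(vals, orient="index") for tag, vals in rows.items()}


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis described by ``config``."""
    stage_log: list[dict] = []

    def stage(name: str, fn):
        t0 = time.perf_counter()
        out = fn()
        dt = time.perf_counter() - t0
        stage_log.append({"stage": name, "seconds": round(dt, 3)})
        logger.info("stage %-22s %.2fs", name, dt)
        return out

    def _cohort():
        if config.mode == "synthetic":
            if config.cohort_spec_path:
                spec = CohortSpec.from_yaml(config.cohort_spec_path)
            else:
                spec = build_default_cohort_spec(seed=config.seeds.cohort)
            cases, _ = generate_cohort(spec)
            return cases
        return _load_real_cohort(config)

    cases = stage("cohort", _cohort)
    cases, exclusions = stage(
        "eligibility_filter", lambda: pio.filter_eligible(cases, config.min_voxels)
    )
    if len(cases) < 4:
        raise RuntimeError(f"only {len(cases)} eligible cases; cannot analyze")

    disc = DiscretizationConfig(**config.discretization.model_dump())
    tables = stage("feature_extraction", lambda: _extract_tables(cases, disc))

    reduced_tables: dict[str, pd.DataFrame] = {}
    reduction_reports: dict[str, ReductionReport] = {}
    for tag in ("SUV", "TBR"):
        retained, report = stage(
            f"redundancy_{tag}",
            lambda tag=tag: reduce_redundancy(
                tables[tag], config.redundancy_threshold, config.strict_redundancy
            ),
        )
        reduced_tables[tag] = tables[tag][retained]
        reduction_reports[tag] = report

    if config.bonferroni_policy == "fixed":
        m = int(config.bonferroni_m)
    else:  # highest non-redundant feature count across datasets
        m = max(len(t.columns) for t in reduced_tables.values())

    records = [c.record for c in cases]
    labels = {
        "sex": {r.patient_id: r.sex for r in records},
        "idh": {r.patient_id: r.idh for r in records},
    }
    split_plans = {
        labeling: stage(
            f"splits_{labeling}",
            lambda labeling=labeling: make_mc_splits(
                records, labeling, config.n_folds, config.seeds.splits
            ),
        )
        for labeling in ("sex", "idh")
    }

    fold_scores = pd.concat(
        [
            stage(
                f"fold_scores_{labeling}",
                lambda labeling=labeling: score_folds(
                    reduced_tables, split_plans[labeling], labels[labeling],
                    seed=config.seeds.forest,
                ),
            )
            for labeling in ("sex", "idh")
        ],
        ignore_index=True,
    )

    rankings = [
        stage(
            f"ranking_{tag}_{labeling}",
            lambda tag=tag, labeling=labeling: rank_features(
                reduced_tables[tag], split_plans[labeling], labels[labeling],
                dataset=tag, k=config.k,
                occurrence_threshold=config.occurrence_threshold,
                alpha=config.alpha, bonferroni_m=m,
            ),
        )
        for labeling in ("sex", "idh")
        for tag in ("SUV", "TBR")
    ]

    subgroups = stage(
        "subgroup_summary",
        lambda: subgroup_summary(tables, records, config.summary_features),
    )
    return PipelineResult(
        config=config,
        cases=cases,
        exclusions=exclusions,
        feature_tables=tables,
        reduced_tables=reduced_tables,
        reduction_reports=reduction_reports,
        bonferroni_m=m,
        split_plans=split_plans,
        fold_scores=fold_scores,
        rankings=rankings,
        subgroups=subgroups,
        stage_log=stage_log,
    )


def _demographics(result: PipelineResult) -> pd.DataFrame:
    """Cohort characteristics table (one row per parameter x sex)."""
    rows = []
    per_patient = []
    for case in result.cases:
        bg_mean, _ = pio.background_stats(case.volume, case.background)
        per_patient.append(
            {
                "patient_id": case.record.patient_id,
                "sex": case.record.sex,
                "idh": case.record.idh,
                "tumor_suv": float(case.volume.data[case.lesion.data].mean()),
                "cba_suv": bg_mean,
            }
        )
    df = pd.DataFrame(per_patient)
    for sex, g in df.groupby("sex"):
        rows.append(
            {
                "sex": sex,
                "n": len(g),
                "idh_positive": int((g["idh"] == "+").sum()),
                "idh_negative": int((g["idh"] == "-").sum()),
                "tumor_suv_mean": g["tumor_suv"].mean(),
                "tumor_suv_sd": g["tumor_suv"].std(ddof=1),
                "cba_suv_mean": g["cba_suv"].mean(),
                "cba_suv_sd": g["cba_suv"].std(ddof=1),
            }
        )
    return pd.DataFrame(rows)


def _ranking_table(result: PipelineResult, labeling: str) -> pd.DataFrame:
    frames = []
    for rk in result.rankings:
        if rk.labeling != labeling:
            continue
        t = rk.table.copy()
        if t.empty:
            t = pd.DataFrame(
                [{"feature": "(no feature exceeded occurrence threshold)",
                  "occurrence": np.nan, "U": np.nan, "p": np.nan, "significant": False}]
            )
        t.insert(0, "dataset", rk.dataset)
        t["mc_selected_features"] = rk.n_selected
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def _scatter_figure(scores: pd.DataFrame, labeling: str, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for tag, marker in (("SUV", "o"), ("TBR", "^")):
        sub = scores[(scores["dataset"] == tag) & (scores["labeling"] == labeling)]
        ax.scatter(sub["borderline"], sub["outlier"], s=12, alpha=0.6,
                   marker=marker, label=tag)
    ax.set_xlabel("borderline score (Tomek-link fraction)")
    ax.set_ylabel("outlier score (isolation forest)")
    ax.set_title(f"MC training subsets, {labeling} labeling")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _occurrence_figure(result: PipelineResult, labeling: str, path: Path) -> None:
    rks = [r for r in result.rankings if r.labeling == labeling]
    fig, axes = plt.subplots(1, len(rks), figsize=(5 * len(rks), 4), squeeze=False)
    for ax, rk in zip(axes[0], rks):
        top = rk.occurrence.sort_values(ascending=False).head(10)
        ax.barh(top.index[::-1], top.values[::-1])
        ax.set_xlabel("MC occurrence rate")
        ax.set_title(f"{rk.dataset}, {labeling}")
        ax.axvline(rk.occurrence_threshold, color="red", ls="--", lw=1)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_reports(result: PipelineResult, out_dir: str | Path, overwrite: bool = False) -> list[Path]:
    """Write tables, figures and the JSON report bundle.

    Refuses to write into a non-empty directory unless ``overwrite``.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(
            f"output directory {out} is not empty; pass overwrite=True to replace"
        )
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_csv(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, index=False)
        written.append(p)

    save_csv(_demographics(result), "demographics.csv")
    save_csv(_ranking_table(result, "sex"), "ranking_sex.csv")
    save_csv(_ranking_table(result, "idh"), "ranking_idh.csv")
    save_csv(result.subgroups, "subgroup_summary.csv")
    save_csv(result.fold_scores, "fold_scores.csv")
    if not result.exclusions.empty:
        save_csv(result.exclusions, "exclusions.csv")

    for labeling in ("sex", "idh"):
        p = out / f"borderline_outlier_{labeling}.png"
        _scatter_figure(result.fold_scores, labeling, p)
        written.append(p)
    _occurrence_figure(result, "sex", out / "occurrence_sex.png")
    _occurrence_figure(result, "idh", out / "occurrence_idh.png")
    written += [out / "occurrence_sex.png", out / "occurrence_idh.png"]

    threshold, displayed = bonferroni_threshold(
        result.config.alpha, result.bonferroni_m
    )
    doc = {
        "config": result.config.model_dump(),
        "n_patients": len(result.cases),
        "exclusions": result.exclusions.to_dict(orient="records"),
        "bonferroni": {
            "m": result.bonferroni_m,
            "alpha": result.config.alpha,
            "threshold": threshold,
            "displayed": displayed,
        },
        "reduction": {
            tag: rep.to_dict() for tag, rep in result.reduction_reports.items()
        },
        "split_plans": {
            labeling: [h for _, h in plan.folds]
            for labeling, plan in result.split_plans.items()
        },
        "fold_scores": result.fold_scores.to_dict(orient="records"),
        "rankings": [
            {
                "dataset": rk.dataset,
                "labeling": rk.labeling,
                "mc_selected_features": rk.n_selected,
                "occurrence": rk.occurrence.to_dict(),
                "high_ranking": rk.high_ranking,
                "tests": rk.table.to_dict(orient="records"),
            }
            for rk in result.rankings
        ],
        "subgroups": result.subgroups.where(pd.notna(result.subgroups), None).to_dict(
            orient="records"
        ),
        # stage names only: timings stay out so identical runs write
        # byte-identical reports
        "stages": [s["stage"] for s in result.stage_log],
    }
    validate_report(doc)
    p = out / "report.json"
    p.write_text(json.dumps(doc, indent=1, default=float))
    written.append(p)
    return written
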