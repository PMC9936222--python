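"""Aligned Monte-Carlo resampling and per-fold diagnostics.

Each fold holds out exactly one patient per class; holdout pairs are
sampled uniformly without replacement from all cross-class pairs, so no
fold configuration repeats. The identical plan is reused for the SUV
and TBR feature tables ("aligned" splits). Per-fold training subsets
are scored with a Tomek-link borderline fraction and an
isolation-forest outlier score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import IsolationForest

from .io import PatientRecord

__all__ = [
    "SplitPlan",
    "make_mc_splits",
    "tomek_borderline",
    "iforest_outlier",
    "score_folds",
]

DEFAULT_N_FOLDS = 100
DEFAULT_N_TREES = 100


@dataclass
class SplitPlan:
    """Monte-Carlo fold plan for one labeling (sex or IDH status)."""

    labeling: Literal["sex", "idh"]
    folds: list[tuple[list[str], list[str]]]  # (train ids, holdout ids) per fold
    seed: int

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "labeling": self.labeling,
            "seed": self.seed,
            "folds": [{"train": t, "holdout": h} for t, h in self.folds],
        }
        Path(path).write_text(json.dumps(doc, indent=1))


def _labels_of(records: Sequence[PatientRecord], labeling: str) -> dict[str, str]:
    if labeling == "sex":
        return {r.patient_id: r.sex for r in records}
    if labeling == "idh":
        return {r.patient_id: r.idh for r in records}
    raise ValueError(f"unknown labeling {labeling!r}")


def make_mc_splits(
    records: Sequence[PatientRecord],
    labeling: Literal["sex", "idh"],
    n_folds: int = DEFAULT_N_FOLDS,
    seed: int = 0,
) -> SplitPlan:
    """Build ``n_folds`` distinct leave-one-per-class-out configurations.

    Raises if more folds are requested than distinct cross-class pairs
    exist (pigeonhole).
    """
    labels = _labels_of(records, labeling)
    classes = sorted(set(labels.values()))
    if len(classes) != 2:
        raise ValueError(f"labeling {labeling!r} must have exactly 2 classes, got {classes}")
    ids_a = sorted(pid for pid, l in labels.items() if l == classes[0])
    ids_b = sorted(pid for pid, l in labels.items() if l == classes[1])
    pairs = [(a, b) for a in ids_a for b in ids_b]
    if n_folds > len(pairs):
        raise ValueError(
            f"requested {n_folds} folds but only {len(pairs)} distinct "
            f"holdout configurations exist"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pairs), size=n_folds, replace=False)
    all_ids = sorted(labels)
    folds = []
    for idx in chosen:
        holdout = list(pairs[idx])
        train = [pid for pid in all_ids if pid not in holdout]
        folds.append((train, holdout))
    return SplitPlan(labeling=labeling, folds=folds, seed=seed)


def _zscore(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def tomek_borderline(
    X: np.ndarray | pd.DataFrame,
    y: Sequence,
    standardize: bool = True,
) -> float:
    """Fraction of samples participating in a Tomek link.

    Features are z-scored column-wise (toggleable); the nearest
    neighbour under Euclidean distance is found per sample with ties
    broken toward the lowest sample index; a Tomek link is a mutual
    nearest-neighbour pair with opposite labels.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    if len(set(y.tolist())) < 2:
        raise ValueError("tomek_borderline requires both classes present")
    if standardize:
        X = _zscore(X)
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    nn = np.argmin(d2, axis=1)  # argmin returns the lowest index on ties
    in_link = np.zeros(n, dtype=bool)
    for i in range(n):
        j = nn[i]
        if nn[j] == i and y[i] != y[j]:
            in_link[i] = in_link[j] = True
    return float(in_link.mean())


def iforest_outlier(
    X: np.ndarray | pd.DataFrame,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    subsample: int | None = None,
) -> tuple[np.ndarray, float]:
    """Isolation-forest anomaly scores s(x) = 2^(-E[h(x)]/c(psi)).

    Returns per-sample scores in (0, 1) and their mean (the fold-level
    outlier score). Subsample defaults to min(256, n).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("iforest_outlier requires at least 2 samples")
    psi = min(256, n) if subsample is None else min(subsample, n)
    forest = IsolationForest(
        n_estimators=n_trees, max_samples=psi, random_state=seed
    ).fit(X)
    # sklearn's score_samples returns the negated anomaly score of the
    # original formulation; negate back to s(x) in (0, 1)
    scores = -forest.score_samples(X)
    return scores, float(scores.mean())


def score_folds(
    tables: dict[str, pd.DataFrame],
    plan: SplitPlan,
    labels: dict[str, str],
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
) -> pd.DataFrame:
    """Borderline/outlier scores of every fold's training subset.

    ``tables`` maps dataset tags (SUV/TBR) to patient x feature tables
    indexed by patient_id; the same plan is applied to each (aligned
    resampling). Per-fold isolation-forest seeds are derived from
    ``seed`` so folds are independent but reproducible.
    """
    rows = []
    for dataset, X in tables.items():
        for k, (train, _) in enumerate(plan.folds):
            sub = X.loc[train]
            y = [labels[pid] for pid in train]
            borderline = tomek_borderline(sub, y)
            _, outlier = iforest_outlier(sub, seed=(seed + k) % (2**31))
            rows.append(
                {
                    "fold": k,
                    "dataset": dataset,
                    "labeling": plan.labeling,
                    "borderline": borderline,
                    "outlier": outlier,
                }
            )
    return pd.DataFrame(rows)
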