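"""Occurrence-based feature ranking and confirmatory inference.

Two-step scheme: per Monte-Carlo fold, features are ranked by R^2
against the binary label (squared point-biserial correlation) on the
training subset and the top k (default 6) are marked as selected; a
feature's occurrence rate is the fraction of folds selecting it.
Features occurring in more than 90% of folds are confirmed on the full
cohort with a two-sided Mann-Whitney U-test under Bonferroni
correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .manifest import manifest_index
from .resampling import SplitPlan

__all__ = [
    "RankingResult",
    "r2_scores",
    "select_top_k",
    "occurrence_rates",
    "high_ranking",
    "mwu_test",
    "bonferroni_threshold",
    "subgroup_summary",
    "rank_features",
]

DEFAULT_K = 6
DEFAULT_OCCURRENCE_THRESHOLD = 0.90
DEFAULT_ALPHA = 0.05
EXACT_MWU_MAX_N = 20


def r2_scores(X: pd.DataFrame, y: Sequence) -> pd.Series:
    """Per-feature R^2 = squared Pearson correlation with the 0/1 label.

    Constant features score 0 by convention.
    """
    y01 = _binary(y)
    if y01.std() == 0:
        raise ValueError("r2_scores requires both classes present")
    V = X.to_numpy(dtype=float)
    Vc = V - V.mean(axis=0)
    yc = y01 - y01.mean()
    denom = np.sqrt(np.sum(Vc**2, axis=0) * np.sum(yc**2))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Vc.T @ yc) / denom
    r[~np.isfinite(r)] = 0.0
    return pd.Series(r**2, index=X.columns)


def _binary(y: Sequence) -> np.ndarray:
    levels = sorted(set(y))
    if len(levels) > 2:
        raise ValueError(f"expected a binary label, got {levels}")
    return np.array([levels.index(v) for v in y], dtype=float)


def select_top_k(scores: pd.Series, k: int = DEFAULT_K) -> list[str]:
    """The k best-scoring features, ties broken by manifest order."""
    if len(scores) < k:
        raise ValueError(f"need at least {k} features, got {len(scores)}")
    order = manifest_index()
    ranked = sorted(
        scores.index,
        key=lambda c: (-scores[c], order.get(c, len(order)), c),
    )
    return ranked[:k]


def occurrence_rates(per_fold_selections: Sequence[Sequence[str]]) -> pd.Series:
    """Fraction of folds in which each ever-selected feature appears."""
    if len(per_fold_selections) == 0:
        raise ValueError("no fold selections given")
    counts: dict[str, int] = {}
    for sel in per_fold_selections:
        for f in sel:
            counts[f] = counts.get(f, 0) + 1
    order = manifest_index()
    names = sorted(counts, key=lambda c: (order.get(c, len(order)), c))
    return pd.Series(
        {f: counts[f] / len(per_fold_selections) for f in names}, dtype=float
    )


def high_ranking(
    rates: pd.Series, threshold: float = DEFAULT_OCCURRENCE_THRESHOLD, strict: bool = True
) -> list[str]:
    """Features with occurrence rate above the threshold (strictly by default)."""
    keep = rates > threshold if strict else rates >= threshold
    return rates.index[keep].tolist()


def mwu_test(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U-test.

    Returns (U, p) with U = min(U_a, U_b). The p-value is exact (full
    enumeration of the null distribution) when the combined sample size
    is at most 20 and there are no ties, otherwise a normal
    approximation with tie and continuity corrections is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    exact = (a.size + b.size <= EXACT_MWU_MAX_N) and not has_ties
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    u_a = float(res.statistic)
    u = min(u_a, a.size * b.size - u_a)
    return u, float(res.pvalue)


def bonferroni_threshold(alpha: float, m: int) -> tuple[float, float]:
    """Corrected significance level alpha/m.

    Returns (threshold, displayed) where ``displayed`` rounds to 4
    decimals for reporting; decisions use the unrounded value.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"Bonferroni factor must be >= 1, got {m}")
    t = alpha / m
    return t, round(t, 4)


@dataclass
class RankingResult:
    """Outcome of the two-step ranking for one dataset x labeling."""

    dataset: str
    labeling: str
    k: int
    occurrence_threshold: float
    alpha: float
    bonferroni_m: int
    per_fold_selections: list[list[str]]
    occurrence: pd.Series
    high_ranking: list[str]
    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    # table columns: feature, occurrence, U, p, significant

    @property
    def n_selected(self) -> int:
        """Number of distinct features ever selected across folds."""
        return len(self.occurrence)


def rank_features(
    X: pd.DataFrame,
    plan: SplitPlan,
    labels: dict[str, str],
    dataset: str,
    k: int = DEFAULT_K,
    occurrence_threshold: float = DEFAULT_OCCURRENCE_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    bonferroni_m: int | None = None,
) -> RankingResult:
    """Run the per-fold R^2 ranking and full-cohort confirmation.

    ``X`` is a patient x feature table indexed by patient_id,
    restricted to the non-redundant features; ``bonferroni_m`` defaults
    to the number of features in ``X``. The confirmatory Mann-Whitney
    test compares the two label groups on the full cohort.
    """
    m = bonferroni_m if bonferroni_m is not None else X.shape[1]
    selections: list[list[str]] = []
    for train, _ in plan.folds:
        scores = r2_scores(X.loc[train], [labels[pid] for pid in train])
        selections.append(select_top_k(scores, k))
    rates = occurrence_rates(selections)
    confirmed = high_ranking(rates, occurrence_threshold)
    threshold, _ = bonferroni_threshold(alpha, m)

    classes = sorted(set(labels.values()))
    ids_a = [pid for pid in X.index if labels[pid] == classes[0]]
    ids_b = [pid for pid in X.index if labels[pid] == classes[1]]
    rows = []
    for feat in confirmed:
        u, p = mwu_test(X.loc[ids_a, feat], X.loc[ids_b, feat])
        rows.append(
            {
                "feature": feat,
                "occurrence": rates[feat],
                "U": u,
                "p": p,
                "significant": p < threshold,
            }
        )
    table = pd.DataFrame(rows, columns=["feature", "occurrence", "U", "p", "significant"])
    if not table.empty:
        table = table.sort_values("p", kind="stable").reset_index(drop=True)
    return RankingResult(
        dataset=dataset,
        labeling=plan.labeling,
        k=k,
        occurrence_threshold=occurrence_threshold,
        alpha=alpha,
        bonferroni_m=m,
        per_fold_selections=selections,
        occurrence=rates,
        high_ranking=confirmed,
        table=table,
    )


def subgroup_summary(
    tables: dict[str, pd.DataFrame],
    records: Sequence,
    features: Sequence[str],
) -> pd.DataFrame:
    """Per sex x IDH cell mean and sample SD of selected features.

    One row per (sex, idh, dataset, feature); cells with a single
    patient report SD as missing.
    """
    by_id = {r.patient_id: r for r in records}
    rows = []
    for dataset, X in tables.items():
        for sex in ("F", "M"):
            for idh in ("+", "-"):
                ids = [
                    pid for pid in X.index
                    if by_id[pid].sex == sex and by_id[pid].idh == idh
                ]
                for feat in features:
                    vals = X.loc[ids, feat]
                    rows.append(
                        {
                            "sex": sex,
                            "idh": idh,
                            "dataset": dataset,
                            "feature": feat,
                            "n": len(ids),
                            "mean": float(vals.mean()) if len(ids) else np.nan,
                            "sd": float(vals.std(ddof=1)) if len(ids) > 1 else np.nan,
                        }
                    )
    return pd.DataFrame(rows)
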