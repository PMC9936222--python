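"""Correlation-based feature redundancy reduction.

Features are clustered as connected components of the graph whose edges
join feature pairs with |Pearson r| above the threshold (default 0.85);
each cluster is represented by its highest-variance member. Constant
features cannot carry a correlation and are dropped up front. SUV and
TBR tables are reduced independently by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .manifest import manifest_index

__all__ = ["ReductionReport", "pearson_matrix", "reduce_redundancy"]

DEFAULT_THRESHOLD = 0.85


@dataclass
class ReductionReport:
    threshold: float
    clusters: list[list[str]]
    representatives: list[str]
    retained: list[str]
    dropped_constant: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "clusters": self.clusters,
            "representatives": self.representatives,
            "retained": self.retained,
            "dropped_constant": self.dropped_constant,
        }


def pearson_matrix(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Feature x feature Pearson correlations.

    Correlations involving constant columns are set to 0 and those
    columns are reported separately; the diagonal is 1 everywhere.
    """
    if X.shape[0] < 2:
        raise ValueError("need at least 2 patients to compute correlations")
    values = X.to_numpy(dtype=float)
    constant = X.columns[values.std(axis=0) == 0].tolist()
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values, rowvar=False)
    corr = np.atleast_2d(corr)
    corr[~np.isfinite(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    for col in constant:
        i = X.columns.get_loc(col)
        corr[i, :] = 0.0
        corr[:, i] = 0.0
        corr[i, i] = 1.0
    return pd.DataFrame(corr, index=X.columns, columns=X.columns), constant


def _feature_order(columns: list[str]) -> dict[str, int]:
    # manifest order where known, table order for extra columns
    midx = manifest_index()
    return {c: (midx.get(c, len(midx)), i) for i, c in enumerate(columns)}


def reduce_redundancy(
    X: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    strict: bool = True,
) -> tuple[list[str], ReductionReport]:
    """Collapse redundant features to one representative per cluster.

    Clusters are connected components of the |r| > threshold graph
    (``strict=False`` uses >=); the representative is the member with
    the highest sample variance, ties broken by manifest order.
    Constant columns are dropped. Returns the retained identifiers in
    manifest order and a full report.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    corr, constant = pearson_matrix(X)
    cols = [c for c in X.columns if c not in constant]
    order = _feature_order(list(X.columns))

    sub = corr.loc[cols, cols].to_numpy()
    adj = np.abs(sub) > threshold if strict else np.abs(sub) >= threshold
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)

    variances = X[cols].var(ddof=1)
    clusters: list[list[str]] = []
    representatives: list[str] = []
    for comp in range(n_comp):
        members = sorted(
            (c for c, l in zip(cols, labels) if l == comp), key=order.__getitem__
        )
        clusters.append(members)
        best = max(members, key=lambda c: (variances[c], [-v for v in order[c]]))
        representatives.append(best)

    retained = sorted(representatives, key=order.__getitem__)
    report = ReductionReport(
        threshold=threshold,
        clusters=clusters,
        representatives=representatives,
        retained=retained,
        dropped_constant=constant,
    )
    return retained, report
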