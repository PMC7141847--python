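"""Clustering evaluation metrics, applied as a final method list.

Metrics are treated as just another pipeline step: each maps a
:class:`ClusteringResult` to a numeric scalar, so they chain through
``apply_methods`` and the tidy export works unchanged.

The adjusted Rand index follows the Hubert–Arabie chance-corrected
pair-counting form computed from the contingency table N = (n_ij) of the two
partitions:

    ARI = (Σ_ij C(n_ij,2) − E) / (½ [Σ_i C(a_i,2) + Σ_j C(b_j,2)] − E),
    E   = Σ_i C(a_i,2) · Σ_j C(b_j,2) / C(n,2),

where a_i, b_j are the row/column sums. ARI is 1 for identical partitions,
concentrates near 0 for independent ones, and can be negative for
disagreement worse than chance.

Mean silhouette width uses Euclidean distance on a caller-supplied
embedding: s(i) = (b(i) − a(i)) / max(a(i), b(i)) with a(i) the mean
intra-cluster distance and b(i) the mean distance to the nearest other
cluster; singleton clusters score 0 (Rousseeuw's convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_samples

from .errors import UndefinedMetricError
from .registry import MethodList, make_method_list

__all__ = [
    "ClusteringResult",
    "adjusted_rand_index",
    "silhouette_width",
    "cluster_count_deviation",
    "metrics_as_method_list",
]


@dataclass(frozen=True)
class ClusteringResult:
    """Output contract of a clustering step.

    ``assigned`` and ``truth`` are aligned to ``cell_ids``; ``embedding``
    (cells x dims) is the coordinate matrix silhouette is evaluated on.
    """

    cell_ids: tuple[str, ...]
    assigned: tuple
    truth: tuple
    embedding: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n = len(self.cell_ids)
        if len(self.assigned) != n or len(self.truth) != n:
            raise ValueError("assigned/truth must align with cell_ids")
        if n == 0:
            raise ValueError("empty clustering result")
        if self.embedding is not None and len(self.embedding) != n:
            raise ValueError("embedding must have one row per cell")


def _contingency(a: Sequence, b: Sequence) -> np.ndarray:
    sa = pd.Series(list(a))
    sb = pd.Series(list(b))
    return pd.crosstab(sa, sb).to_numpy()


def _comb2(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x * (x - 1.0) / 2.0


def _same_partition(a: Sequence, b: Sequence) -> bool:
    """True iff a and b induce the same partition up to label renaming."""
    tab = _contingency(a, b)
    return bool(np.all((tab > 0).sum(axis=0) == 1) and np.all((tab > 0).sum(axis=1) == 1))


def adjusted_rand_index(a: Sequence, b: Sequence) -> float:
    """Hubert–Arabie adjusted Rand index between two label vectors.

    Symmetric and invariant to relabeling of either argument. When the
    chance-correction denominator is 0 (both partitions all singletons, or
    both a single cluster) the formula is 0/0; by convention this returns
    1.0 when the partitions are identical and 0.0 otherwise.
    """
    a = list(a)
    b = list(b)
    if len(a) != len(b):
        raise ValueError(f"label vectors differ in length: {len(a)} vs {len(b)}")
    if len(a) < 2:
        raise ValueError("ARI requires at least 2 observations")
    tab = _contingency(a, b)
    n = float(len(a))
    sum_ij = _comb2(tab).sum()
    sum_a = _comb2(tab.sum(axis=1)).sum()
    sum_b = _comb2(tab.sum(axis=0)).sum()
    expected = sum_a * sum_b / _comb2(np.array(n)).item()
    denom = 0.5 * (sum_a + sum_b) - expected
    if denom == 0.0:
        return 1.0 if _same_partition(a, b) else 0.0
    return float((sum_ij - expected) / denom)


def silhouette_width(embedding: np.ndarray, assigned: Sequence) -> float:
    """Mean silhouette width over cells, Euclidean distance.

    Raises :class:`UndefinedMetricError` for a single cluster (the score is
    undefined); within a benchmark this surfaces as a per-row failure
    outcome rather than aborting the run.
    """
    embedding = np.asarray(embedding, dtype=float)
    if embedding.ndim == 1:
        embedding = embedding[:, None]
    labels = pd.factorize(np.asarray(list(assigned), dtype=object))[0]
    if len(labels) != len(embedding):
        raise ValueError("embedding and labels must have equal length")
    n_clusters = len(np.unique(labels))
    if n_clusters < 2:
        raise UndefinedMetricError(
            "silhouette width is undefined for a single cluster"
        )
    if n_clusters >= len(labels):
        # all singletons: every s(i) is 0 by the singleton convention
        return 0.0
    return float(np.mean(silhouette_samples(embedding, labels, metric="euclidean")))


def cluster_count_deviation(assigned: Sequence, truth: Sequence) -> int:
    """(#distinct assigned clusters) − (#distinct true groups)."""
    return len(set(assigned)) - len(set(truth))


def _ari_metric(result: ClusteringResult) -> float:
    return adjusted_rand_index(result.assigned, result.truth)


def _silhouette_metric(result: ClusteringResult) -> float:
    if result.embedding is None:
        raise UndefinedMetricError(
            "clustering result carries no embedding for silhouette"
        )
    return silhouette_width(result.embedding, result.assigned)


def _n_cluster_dev_metric(result: ClusteringResult) -> int:
    return cluster_count_deviation(result.assigned, result.truth)


_METRICS = {
    "ari": _ari_metric,
    "silhouette": _silhouette_metric,
    "n_cluster_dev": _n_cluster_dev_metric,
}


def metrics_as_method_list(
    names: Sequence[str] = ("ari",), step_name: str = "metric"
) -> MethodList:
    """Package evaluation metrics as a method list for ``apply_methods``.

    Each metric maps a :class:`ClusteringResult` to a scalar, so chaining
    this list multiplies rows by ``len(names)`` and leaves the table ready
    for ``collect_results(scalar_only=True)``.
    """
    unknown = [n for n in names if n not in _METRICS]
    if unknown:
        raise ValueError(
            f"unknown metrics {unknown}; available: {sorted(_METRICS)}"
        )
    if not names:
        raise ValueError("at least one metric name is required")
    return make_method_list(step_name, [(n, _METRICS[n]) for n in names])
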