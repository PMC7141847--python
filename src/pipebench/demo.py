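"""Stand-in method lists and the 2 x 4 x 3 x 3 demonstration benchmark.

Reproduces the structure of a multi-step clustering benchmark: 2 datasets
pass through 4 normalization options, 3 imputation options and 3 clustering
methods — 72 dataset x method combinations — and each combination is scored
by adjusted Rand index against the ground-truth cell groups. The individual
methods are lightweight stand-ins (CPM scaling, kNN smoothing, k-means, ...)
rather than wrappers around external toolkits: the point of the benchmark is
the combinatorial machinery and the evaluation, not the specific methods.

Inter-step state is a :class:`PipelineState` bundle (expression matrix plus
identifiers and labels) so downstream clusterers and metrics have everything
they need; clustering wrappers apply a log1p variance-stabilising transform
and PCA internally, as real clustering wrappers do.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from functools import partial
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .core import (
    BenchmarkTable,
    apply_methods,
    begin_benchmark,
    collect_results,
    pipeline_id,
)
from .metrics import ClusteringResult, metrics_as_method_list
from .registry import MethodList, make_method_list, wrap_method
from .sc_data import SCDataset

__all__ = [
    "PipelineState",
    "demo_method_lists",
    "run_demo",
    "top_k_per_clusterer",
    "plot_top_k",
]


@dataclass(frozen=True)
class PipelineState:
    """Common inter-step payload: expression matrix + metadata.

    ``matrix`` is genes x cells on whatever scale the preceding steps left
    it (raw counts, CPM, log-CPM, smoothed...).
    """

    matrix: np.ndarray
    gene_ids: tuple[str, ...]
    cell_ids: tuple[str, ...]
    labels: Optional[tuple[str, ...]]
    name: str


def state_from_dataset(d: SCDataset) -> PipelineState:
    return PipelineState(matrix=np.asarray(d.counts, dtype=float),
                         gene_ids=d.gene_ids, cell_ids=d.cell_ids,
                         labels=d.labels, name=d.name)


def _with_matrix(state: PipelineState, matrix: np.ndarray) -> PipelineState:
    return replace(state, matrix=np.asarray(matrix, dtype=float))


def _depth_equalize(matrix: np.ndarray) -> np.ndarray:
    """Scale each cell (column) to the median column total.

    Emulates the internal depth normalization most single-cell clustering
    tools apply in their own preprocessing; on matrices whose columns
    already have (near-)equal totals this is (near-)identity.
    """
    totals = matrix.sum(axis=0)
    totals = np.where(totals == 0, 1.0, totals)
    return matrix / totals * np.median(totals)


def _cells_pca(matrix: np.ndarray, n_components: int = 10,
               log: bool = False, scale: bool = False,
               seed: int = 0) -> np.ndarray:
    """PCA coordinates of cells (columns of the genes x cells matrix).

    ``log`` applies depth equalization plus log1p variance stabilisation;
    ``scale`` z-scores each gene. Together they make the embedding robust
    to the scale the preceding normalization left the matrix on.
    """
    x = matrix.T
    if log:
        x = np.log1p(_depth_equalize(matrix).T)
    if scale:
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        x = (x - mu) / sd
    n_comp = min(n_components, x.shape[0] - 1, x.shape[1])
    n_comp = max(n_comp, 1)
    return PCA(n_components=n_comp, random_state=seed).fit_transform(x)


# ---------------------------------------------------------------------------
# Normalization stand-ins (PipelineState -> PipelineState)
# ---------------------------------------------------------------------------


def _identity(state: PipelineState) -> PipelineState:
    return state


def norm_cpm(state: PipelineState) -> PipelineState:
    """Counts-per-million library-size scaling."""
    totals = state.matrix.sum(axis=0)
    totals = np.where(totals == 0, 1.0, totals)
    return _with_matrix(state, state.matrix / totals * 1e6)


def norm_logcpm(state: PipelineState) -> PipelineState:
    """log1p of counts-per-million."""
    return _with_matrix(norm_cpm(state), np.log1p(norm_cpm(state).matrix))


def norm_medratio(state: PipelineState) -> PipelineState:
    """Median-of-ratios size-factor normalization.

    The per-gene reference is the geometric mean over cells with non-zero
    counts (the "poscounts" variant), so the estimator is defined on sparse
    droplet-like data; each cell is divided by the median ratio of its
    counts to the reference.
    """
    m = state.matrix
    with np.errstate(divide="ignore"):
        logm = np.where(m > 0, np.log(np.where(m > 0, m, 1.0)), 0.0)
    n_pos = (m > 0).sum(axis=1)
    ref = np.where(n_pos > 0, np.exp(logm.sum(axis=1) / np.maximum(n_pos, 1)), 0.0)
    usable = ref > 0
    if not usable.any():
        raise ValueError("median-of-ratios undefined: all-zero matrix")
    ratios = m[usable, :] / ref[usable, None]
    factors = np.zeros(m.shape[1])
    for j in range(m.shape[1]):
        col = ratios[:, j]
        col = col[col > 0]
        factors[j] = np.median(col) if col.size else 1.0
    factors = np.where(factors <= 0, 1.0, factors)
    factors = factors / np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return _with_matrix(state, m / factors[None, :])


# ---------------------------------------------------------------------------
# Imputation stand-ins (PipelineState -> PipelineState)
# ---------------------------------------------------------------------------


def _knn_indices(matrix: np.ndarray, k: int, seed: int) -> np.ndarray:
    emb = _cells_pca(matrix, n_components=10, log=True, scale=True, seed=seed)
    k_eff = min(k, emb.shape[0] - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(emb)
    return nn.kneighbors(emb, return_distance=False)  # self in column 0


def impute_knn_smooth(state: PipelineState, k: int = 5,
                      seed: int = 0) -> PipelineState:
    """Average each cell with its k nearest neighbours in PCA space."""
    idx = _knn_indices(state.matrix, k, seed)
    smoothed = state.matrix[:, idx].mean(axis=2)
    return _with_matrix(state, smoothed)


def impute_magic_lite(state: PipelineState, k: int = 5,
                      seed: int = 0) -> PipelineState:
    """One-step diffusion: row-normalized kNN-graph smoothing."""
    idx = _knn_indices(state.matrix, k, seed)
    n = state.matrix.shape[1]
    p = np.zeros((n, n))
    rows = np.repeat(np.arange(n), idx.shape[1])
    p[rows, idx.ravel()] = 1.0
    p = p / p.sum(axis=1, keepdims=True)
    return _with_matrix(state, state.matrix @ p.T)


# ---------------------------------------------------------------------------
# Clustering stand-ins (PipelineState -> ClusteringResult)
# ---------------------------------------------------------------------------


def _true_k(state: PipelineState) -> int:
    if state.labels is None:
        raise ValueError(
            f"dataset {state.name!r} has no ground-truth labels; "
            "clustering stand-ins read k from labels"
        )
    return len(set(state.labels))


def _as_result(state: PipelineState, assigned: np.ndarray,
               embedding: np.ndarray) -> ClusteringResult:
    return ClusteringResult(
        cell_ids=state.cell_ids,
        assigned=tuple(int(a) for a in assigned),
        truth=tuple(state.labels),
        embedding=embedding,
    )


def cluster_kmeans(state: PipelineState, seed: int = 0) -> ClusteringResult:
    """k-means on log1p + PCA coordinates, k = true group count."""
    emb = _cells_pca(state.matrix, log=True, scale=True, seed=seed)
    km = KMeans(n_clusters=_true_k(state), random_state=seed, n_init=10)
    return _as_result(state, km.fit_predict(emb), emb)


def cluster_hclust_ward(state: PipelineState, seed: int = 0) -> ClusteringResult:
    """Ward agglomerative clustering on log1p + PCA, cut at true k."""
    emb = _cells_pca(state.matrix, log=True, scale=True, seed=seed)
    hc = AgglomerativeClustering(n_clusters=_true_k(state), linkage="ward")
    return _as_result(state, hc.fit_predict(emb), emb)


def cluster_graph_louvain_lite(state: PipelineState, k: int = 10,
                               seed: int = 0) -> ClusteringResult:
    """kNN graph + greedy modularity communities.

    The number of communities is data-driven (not fixed to true k), which is
    what makes the cluster-count-deviation metric informative.
    """
    emb = _cells_pca(state.matrix, log=True, scale=True, seed=seed)
    _true_k(state)  # enforce the labelled-data precondition
    k_eff = min(k, emb.shape[0] - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(emb)
    idx = nn.kneighbors(emb, return_distance=False)
    graph = nx.Graph()
    graph.add_nodes_from(range(emb.shape[0]))
    for i in range(emb.shape[0]):
        for j in idx[i, 1:]:
            graph.add_edge(i, int(j))
    communities = nx.community.greedy_modularity_communities(graph)
    assigned = np.zeros(emb.shape[0], dtype=int)
    for ci, members in enumerate(communities):
        assigned[list(members)] = ci
    return _as_result(state, assigned, emb)


# ---------------------------------------------------------------------------
# Method lists and the demonstration benchmark
# ---------------------------------------------------------------------------


def demo_method_lists(seed: int = 0, knn_k: int = 5) -> tuple[MethodList, MethodList, MethodList]:
    """The demo's (normalization, imputation, clustering) method lists.

    Sizes (4, 3, 3): norm = {none, cpm, logcpm, medratio}; impute = {none,
    knn_smooth, magic_lite}; cluster = {kmeans, hclust_ward,
    graph_louvain_lite}. Every "none" entry is the identity on the step's
    state. Stochastic methods bind ``seed`` at registration, so the lists
    are deterministic transforms.
    """
    norm = make_method_list("norm_method", [
        ("none", wrap_method(_identity, pre_adapter=state_from_dataset)),
        ("cpm", wrap_method(norm_cpm, pre_adapter=state_from_dataset)),
        ("logcpm", wrap_method(norm_logcpm, pre_adapter=state_from_dataset)),
        ("medratio", wrap_method(norm_medratio, pre_adapter=state_from_dataset)),
    ])
    impute = make_method_list("impute_method", [
        ("none", _identity),
        ("knn_smooth", partial(impute_knn_smooth, k=knn_k, seed=seed)),
        ("magic_lite", partial(impute_magic_lite, k=knn_k, seed=seed)),
    ])
    cluster = make_method_list("cluster_method", [
        ("kmeans", partial(cluster_kmeans, seed=seed)),
        ("hclust_ward", partial(cluster_hclust_ward, seed=seed)),
        ("graph_louvain_lite", partial(cluster_graph_louvain_lite, seed=seed)),
    ])
    return norm, impute, cluster


def run_demo(datasets: Mapping[str, SCDataset], seed: int = 0,
             workers: int = 1,
             metrics: Sequence[str] = ("ari",)) -> BenchmarkTable:
    """Run the full demonstration benchmark on labelled datasets.

    With 2 datasets the table has 2 * 4 * 3 * 3 = 72 rows after the
    clustering step; a single metric keeps it at 72. Per-combination
    failures are captured, never raised.
    """
    for name, d in datasets.items():
        if d.labels is None:
            raise ValueError(f"dataset {name!r} carries no ground-truth labels")
    norm, impute, cluster = demo_method_lists(seed=seed)
    table = begin_benchmark(datasets)
    table = apply_methods(table, norm, workers=workers)
    table = apply_methods(table, impute, workers=workers)
    table = apply_methods(table, cluster, workers=workers)
    table = apply_methods(table, metrics_as_method_list(metrics), workers=workers)
    return table


def top_k_per_clusterer(report: pd.DataFrame, k: int,
                        cluster_col: str = "cluster_method",
                        value_col: str = "value") -> pd.DataFrame:
    """Top-k pipelines per clustering method and dataset, by ARI.

    ``report`` is a tidy table from :func:`collect_results` containing the
    clustering-step column and ARI values. Ties are broken by descending
    ARI then lexicographic pipeline id, so summaries are reproducible.
    Failed rows are excluded from ranking. Returns columns
    (clustering_method, pipeline_id, dataset, ari, rank_within_clusterer).
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    if cluster_col not in report.columns:
        raise ValueError(f"report has no clustering column {cluster_col!r}")
    step_cols = [c for c in report.columns
                 if c not in {"data", "value", "error", "seconds", "metric"}]
    rows = []
    ok = report[report[value_col].notna()].copy()
    ok["pipeline_id"] = ok[step_cols].agg("→".join, axis=1)
    for (clusterer, dataset), grp in ok.groupby([cluster_col, "data"], sort=True):
        grp = grp.sort_values([value_col, "pipeline_id"],
                              ascending=[False, True], kind="mergesort")
        if k > len(grp):
            warnings.warn(
                f"requested top {k} but only {len(grp)} pipelines available "
                f"for {clusterer!r} on {dataset!r}; returning all",
                stacklevel=2,
            )
        top = grp.head(k)
        for rank, (_, row) in enumerate(top.iterrows(), start=1):
            rows.append({
                "clustering_method": clusterer,
                "pipeline_id": row["pipeline_id"],
                "dataset": dataset,
                "ari": float(row[value_col]),
                "rank_within_clusterer": rank,
            })
    return pd.DataFrame.from_records(rows, columns=[
        "clustering_method", "pipeline_id", "dataset", "ari",
        "rank_within_clusterer",
    ])


def plot_top_k(summary: pd.DataFrame, path: str) -> None:
    """Best-effort grouped bar plot of a top-k summary (one panel/dataset)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    datasets = summary["dataset"].unique()
    fig, axes = plt.subplots(1, len(datasets),
                             figsize=(6 * len(datasets), 4), squeeze=False)
    for ax, dataset in zip(axes[0], datasets):
        sub = summary[summary["dataset"] == dataset]
        positions, heights, ticklabels = [], [], []
        pos = 0
        for clusterer, grp in sub.groupby("clustering_method", sort=True):
            for _, row in grp.iterrows():
                positions.append(pos)
                heights.append(row["ari"])
                ticklabels.append(row["pipeline_id"])
                pos += 1
            pos += 1  # gap between clusterer blocks
        ax.bar(positions, heights)
        ax.set_xticks(positions)
        ax.set_xticklabels(ticklabels, rotation=90, fontsize=6)
        ax.set_ylabel("adjusted Rand index")
        ax.set_title(dataset)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
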