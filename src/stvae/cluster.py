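"""Leiden clustering of feature spaces, single-layer and multiplex, with
unbiased hyperparameter tuning and cluster-quality scoring.

Graphs are symmetrised k-NN graphs built on standardized features with
Euclidean distances and stable index tie-breaking. Single-layer clustering is
routed through the same multiplex optimiser code path, so a one-layer
multiplex run is exactly the single-layer result. Tuning maximises the mean
silhouette over a (k, resolution) grid subject to a minimum cluster count
(default 5); multiplex weight tuning inherits per-layer (k, resolution) from
the single-layer optima and scans the weight simplex, scoring each candidate
partition by the unweighted mean of per-modality silhouettes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg as la
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import (adjusted_mutual_info_score, homogeneity_score,
                             silhouette_score)
from sklearn.metrics.pairwise import euclidean_distances

__all__ = [
    "GraphSpec",
    "ClusterResult",
    "JaccardMatchTable",
    "standardize",
    "build_knn_graph",
    "leiden_cluster",
    "tune_single",
    "multiplex_cluster",
    "tune_multiplex_weights",
    "clustering_metrics",
    "jaccard_match",
]


@dataclass
class GraphSpec:
    n_vertices: int
    k: int
    edges: np.ndarray              # (E, 2) int, i < j, lexicographically sorted
    distances: np.ndarray          # (E,) Euclidean edge lengths (record only)
    metric: str = "euclidean"

    def to_igraph(self) -> ig.Graph:
        return ig.Graph(n=self.n_vertices, edges=[tuple(e) for e in self.edges])


@dataclass
class ClusterResult:
    labels: np.ndarray
    n_clusters: int
    k: int | tuple | None = None
    resolution: float | tuple | None = None
    layer_weights: tuple | None = None
    metrics: dict = field(default_factory=dict)
    grid: pd.DataFrame | None = None


@dataclass
class JaccardMatchTable:
    table: pd.DataFrame            # columns: label, cluster, jaccard
    unmatched_clusters: list = field(default_factory=list)
    total_score: float = 0.0


def standardize(features: np.ndarray) -> np.ndarray:
    """Column-wise z-score (population sd); constant columns map to zeros."""
    X = np.asarray(features, dtype=np.float64)
    if X.shape[0] < 2:
        raise ValueError("standardize requires at least 2 rows")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    const = sd == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant column(s) mapped to zeros")
    return (X - mu) / np.where(const, 1.0, sd) * (~const)


def build_knn_graph(features: np.ndarray, k: int) -> GraphSpec:
    """Symmetrised (union) k-NN graph; deterministic, ties by lowest index."""
    X = np.asarray(features, dtype=np.float64)
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < number of points ({n})")
    if k < 1:
        raise ValueError("k must be >= 1")
    D = euclidean_distances(X)
    np.fill_diagonal(D, np.inf)
    idx = np.arange(n)
    pairs = set()
    dist_of = {}
    for i in range(n):
        order = np.lexsort((idx, D[i]))[:k]      # stable: distance, then index
        for j in order:
            e = (i, int(j)) if i < j else (int(j), i)
            pairs.add(e)
            dist_of[e] = D[i, j]
    edges = np.array(sorted(pairs), dtype=np.int64).reshape(-1, 2)
    dists = np.array([dist_of[tuple(e)] for e in edges])
    return GraphSpec(n_vertices=n, k=k, edges=edges, distances=dists)


def _relabel(membership: np.ndarray) -> np.ndarray:
    """Contiguous ids ordered by first occurrence (deterministic)."""
    out = np.empty(len(membership), dtype=np.int64)
    seen: dict[int, int] = {}
    for i, m in enumerate(membership):
        if m not in seen:
            seen[m] = len(seen)
        out[i] = seen[m]
    return out


def multiplex_cluster(layers: list[GraphSpec],
                      layer_weights: list[float] | tuple,
                      resolutions: list[float] | float,
                      seed: int = 0) -> ClusterResult:
    """Leiden on layered graphs with a common vertex set, optimising the
    layer-weighted sum of per-layer RB-configuration modularities."""
    if len(layers) == 0:
        raise ValueError("no layers given")
    n = layers[0].n_vertices
    if any(l.n_vertices != n for l in layers):
        raise ValueError("all layers must share one vertex set")
    if n == 0:
        raise ValueError("empty graph")
    weights = list(np.atleast_1d(np.asarray(layer_weights, dtype=float)))
    if len(weights) != len(layers):
        raise ValueError("one weight per layer required")
    if any(w < 0 for w in weights) or sum(weights) <= 0:
        raise ValueError("weights must be >= 0 with at least one > 0")
    if np.isscalar(resolutions):
        resolutions = [float(resolutions)] * len(layers)
    parts = [la.RBConfigurationVertexPartition(
        l.to_igraph(), resolution_parameter=float(r))
        for l, r in zip(layers, resolutions)]
    opt = la.Optimiser()
    opt.set_rng_seed(seed)
    opt.optimise_partition_multiplex(parts, layer_weights=weights, n_iterations=-1)
    labels = _relabel(np.asarray(parts[0].membership))
    return ClusterResult(labels=labels, n_clusters=int(labels.max()) + 1,
                         k=tuple(l.k for l in layers),
                         resolution=tuple(resolutions),
                         layer_weights=tuple(weights))


def leiden_cluster(graph: GraphSpec, resolution: float = 1.0,
                   seed: int = 0) -> ClusterResult:
    """Single-layer Leiden; communities are asserted internally connected."""
    res = multiplex_cluster([graph], [1.0], resolution, seed=seed)
    g = graph.to_igraph()
    for c in range(res.n_clusters):
        sub = g.induced_subgraph(np.flatnonzero(res.labels == c))
        if sub.vcount() > 1 and not sub.is_connected():
            raise AssertionError(f"community {c} is not internally connected")
    res.k = graph.k
    res.resolution = resolution
    res.layer_weights = None
    return res


def _silhouette(X: np.ndarray, labels: np.ndarray, seed: int = 0,
                max_cells: int = 5000) -> float | None:
    if len(np.unique(labels)) < 2:
        return None
    if X.shape[0] > max_cells:
        rng = np.random.default_rng([seed, 401])
        sub = rng.choice(X.shape[0], size=max_cells, replace=False)
        X, labels = X[sub], labels[sub]
        if len(np.unique(labels)) < 2:
            return None
    return float(silhouette_score(X, labels, metric="euclidean"))


def tune_single(features: np.ndarray, k_grid=(10, 15, 20, 30, 50),
                resolution_grid=(0.1, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0),
                min_clusters: int = 5, seed: int = 0,
                pre_standardized: bool = False) -> ClusterResult:
    """Grid search over (k, resolution) maximising mean silhouette, subject
    to the minimum cluster count; the full grid table is recorded."""
    X = np.asarray(features, dtype=np.float64) if pre_standardized \
        else standardize(features)
    rows = []
    best = None
    for k in k_grid:
        if k >= X.shape[0]:
            continue
        graph = build_knn_graph(X, k)
        for res in resolution_grid:
            cr = multiplex_cluster([graph], [1.0], res, seed=seed)
            sil = _silhouette(X, cr.labels, seed=seed)
            feasible = cr.n_clusters >= min_clusters and sil is not None
            rows.append({"k": k, "resolution": res, "n_clusters": cr.n_clusters,
                         "silhouette": sil, "feasible": feasible})
            if feasible and (best is None or sil > best[0]):
                cr.k, cr.resolution, cr.layer_weights = k, res, None
                best = (sil, cr)
    grid = pd.DataFrame(rows)
    if best is None:
        top = grid.sort_values("silhouette", ascending=False).head(5)
        raise ValueError(
            "no grid point met the minimum cluster count of "
            f"{min_clusters}; best infeasible candidates:\n{top}")
    sil, cr = best
    cr.metrics["silhouette"] = sil
    cr.grid = grid
    return cr


def tune_multiplex_weights(layer_features: list[np.ndarray],
                           inherited: list[tuple[int, float]],
                           weight_step: float = 0.05,
                           min_clusters: int = 5, seed: int = 0) -> ClusterResult:
    """Two-layer weight scan (w, 1-w) with per-layer (k, resolution)
    inherited from single-layer tuning. Objective: unweighted mean of the
    per-modality silhouettes of the joint partition. Chosen weights are also
    reported as percentages."""
    if len(layer_features) != 2:
        raise ValueError("weight tuning is implemented for two layers")
    Xs = [standardize(f) for f in layer_features]
    graphs = [build_knn_graph(X, k) for X, (k, _) in zip(Xs, inherited)]
    resolutions = [r for _, r in inherited]
    rows = []
    best = None
    grid = np.round(np.arange(0.0, 1.0 + 1e-9, weight_step), 10)
    for w in grid:
        cr = multiplex_cluster(graphs, [w, 1.0 - w], resolutions, seed=seed)
        sils = [_silhouette(X, cr.labels, seed=seed) for X in Xs]
        obj = None if any(s is None for s in sils) else float(np.mean(sils))
        feasible = cr.n_clusters >= min_clusters and obj is not None
        rows.append({"w_layer0": w, "n_clusters": cr.n_clusters,
                     "objective": obj, "feasible": feasible})
        # ties (identical partitions at several weightings) resolve toward
        # the purest weighting, so an uninformative layer is not credited
        key = (obj, max(w, 1.0 - w), w) if feasible else None
        if feasible and (best is None or key > best[0]):
            best = (key, cr)
    gdf = pd.DataFrame(rows)
    if best is None:
        raise ValueError(
            "no weighting met the minimum cluster count of "
            f"{min_clusters}; grid:\n{gdf}")
    key, cr = best
    cr.metrics["mean_silhouette"] = key[0]
    cr.metrics["weights_percent"] = tuple(100.0 * w for w in cr.layer_weights)
    cr.grid = gdf
    return cr


def clustering_metrics(pred: np.ndarray, truth: np.ndarray | None = None,
                       features: np.ndarray | None = None,
                       seed: int = 0) -> dict:
    """Mean silhouette (internal) plus homogeneity and AMI when truth is
    given. A single-cluster partition has undefined silhouette (None) and
    homogeneity 0 by convention."""
    pred = np.asarray(pred)
    out: dict = {}
    if features is not None:
        out["silhouette"] = _silhouette(np.asarray(features, dtype=np.float64),
                                        pred, seed=seed)
    if truth is not None:
        truth = np.asarray(truth)
        if len(truth) != len(pred):
            raise ValueError("pred and truth must be aligned")
        if len(np.unique(pred)) < 2:
            out["homogeneity"] = 0.0
            out["ami"] = 0.0
        else:
            out["homogeneity"] = float(homogeneity_score(truth, pred))
            out["ami"] = float(adjusted_mutual_info_score(truth, pred))
    return out


def jaccard_match(pred: np.ndarray, truth: np.ndarray) -> JaccardMatchTable:
    """Per cluster-label Jaccard scores with the one-to-one Hungarian
    assignment maximising the total; unmatched labels appear with cluster
    None, unmatched clusters are listed."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if len(pred) == 0 or len(pred) != len(truth):
        raise ValueError("pred and truth must be aligned and non-empty")
    labels = pd.unique(truth)
    clusters = pd.unique(pred)
    J = np.zeros((len(labels), len(clusters)))
    for i, l in enumerate(labels):
        in_l = truth == l
        for j, c in enumerate(clusters):
            in_c = pred == c
            inter = np.sum(in_l & in_c)
            union = np.sum(in_l | in_c)
            J[i, j] = inter / union if union else 0.0
    ri, ci = linear_sum_assignment(-J)
    match = {int(r): int(c) for r, c in zip(ri, ci)}
    rows = []
    total = 0.0
    for i, l in enumerate(labels):
        if i in match:
            j = match[i]
            rows.append({"label": l, "cluster": clusters[j], "jaccard": J[i, j]})
            total += J[i, j]
        else:
            rows.append({"label": l, "cluster": None, "jaccard": 0.0})
    unmatched = [clusters[j] for j in range(len(clusters))
                 if j not in match.values()]
    return JaccardMatchTable(table=pd.DataFrame(rows),
                             unmatched_clusters=unmatched, total_score=total)
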