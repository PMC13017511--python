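"""TF activity waves: PCA, metric-compared clustering, silhouette selection.

TFs sharing a dynamic activity profile across ordered cell states form a
"wave". The row-z-scored TF x sample activity matrix is reduced to its
leading principal components, clustered at every (distance metric, k) in a
grid — Euclidean (k-means), Manhattan (k-medians), and Kendall / Pearson /
Spearman correlation distances (PAM k-medoids) — and the model with the
highest average silhouette width (computed with the clustering's own
metric, in PC space) is selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import kendalltau, rankdata
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

__all__ = [
    "METRICS",
    "WaveModel",
    "pca_embed",
    "cluster_with_metric",
    "select_clustering",
    "fit_waves",
]

#: Grid order; also the tie-break order for model selection.
METRICS = ("euclidean", "manhattan", "kendall", "pearson", "spearman")


@dataclass
class WaveModel:
    n_pcs: int
    variance_explained: np.ndarray  # cumulative fractions
    metric: str
    k: int
    assignment: pd.Series           # TF -> wave id in 1..k
    silhouette_table: pd.DataFrame  # index metric, columns k -> avg width


def pca_embed(znorm_scores: pd.DataFrame, n_pcs: int = 10,
              ) -> tuple[pd.DataFrame, np.ndarray]:
    """Column-centered PCA of the TF x sample matrix.

    Returns the TF x n_pcs embedding and the per-component variance
    fractions (nonincreasing). Warns when the retained components explain
    less than 70% of the variance.
    """
    X = znorm_scores.to_numpy(dtype=float)
    if np.ptp(X) == 0:
        raise ValueError("constant matrix has no principal components")
    n_pcs = int(n_pcs)
    if n_pcs > min(X.shape):
        raise ValueError(f"n_pcs={n_pcs} exceeds matrix rank bound "
                         f"{min(X.shape)}")
    pca = PCA(n_components=n_pcs, svd_solver="full")
    emb = pca.fit_transform(X)
    var = pca.explained_variance_ratio_
    if var.sum() < 0.70:
        warnings.warn(f"retained {n_pcs} PCs explain only "
                      f"{var.sum():.1%} of the variance (< 70%)")
    cols = [f"PC{i+1}" for i in range(n_pcs)]
    return pd.DataFrame(emb, index=znorm_scores.index, columns=cols), var


def _corr_distance(X: np.ndarray, metric: str) -> np.ndarray:
    """1 - correlation distance matrix between rows of X."""
    if metric == "pearson":
        c = np.corrcoef(X)
    elif metric == "spearman":
        c = np.corrcoef(np.apply_along_axis(rankdata, 1, X))
    elif metric == "kendall":
        n = X.shape[0]
        c = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                tau = kendalltau(X[i], X[j]).statistic
                c[i, j] = c[j, i] = 0.0 if np.isnan(tau) else tau
    else:
        raise ValueError(f"unknown correlation metric {metric!r}")
    d = 1.0 - np.clip(c, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return d


def _kmedians(X: np.ndarray, k: int, rng: np.random.Generator,
              n_init: int, max_iter: int = 100) -> np.ndarray:
    """Lloyd-style k-medians under the Manhattan distance."""
    n = X.shape[0]
    best_cost, best_labels = np.inf, None
    for _ in range(n_init):
        centers = X[rng.choice(n, size=k, replace=False)].copy()
        labels = np.full(n, -1)
        for _it in range(max_iter):
            d = cdist(X, centers, metric="cityblock")
            new_labels = d.argmin(axis=1)
            if (new_labels == labels).all():
                break
            labels = new_labels
            for c in range(k):
                members = X[labels == c]
                if len(members):
                    centers[c] = np.median(members, axis=0)
        cost = cdist(X, centers, metric="cityblock")[np.arange(n), labels].sum()
        if cost < best_cost:
            best_cost, best_labels = cost, labels
    return best_labels


def _kmedoids(D: np.ndarray, k: int, rng: np.random.Generator,
              n_init: int, max_iter: int = 100) -> np.ndarray:
    """PAM-style k-medoids on a precomputed distance matrix
    (Voronoi iteration: assign to nearest medoid, re-pick each cluster's
    minimizer of within-cluster distance)."""
    n = D.shape[0]
    best_cost, best_labels = np.inf, None
    for _ in range(n_init):
        medoids = rng.choice(n, size=k, replace=False)
        for _ in range(max_iter):
            labels = D[:, medoids].argmin(axis=1)
            new_medoids = medoids.copy()
            for c in range(k):
                members = np.flatnonzero(labels == c)
                if len(members):
                    within = D[np.ix_(members, members)].sum(axis=1)
                    new_medoids[c] = members[within.argmin()]
            if (new_medoids == medoids).all():
                break
            medoids = new_medoids
        labels = D[:, medoids].argmin(axis=1)
        cost = D[np.arange(n), medoids[labels]].sum()
        if cost < best_cost:
            best_cost, best_labels = cost, labels
    return best_labels


def cluster_with_metric(embedding: pd.DataFrame, metric: str, k: int,
                        seed: int = 0, n_init: int = 20,
                        precomputed_distance: np.ndarray | None = None,
                        ) -> tuple[pd.Series, float]:
    """Cluster embedding rows at a given k under one distance metric.

    Euclidean uses k-means, Manhattan k-medians, and the correlation
    metrics PAM k-medoids on the 1-correlation distance; the silhouette is
    computed with the same metric. Returns (assignment with wave ids 1..k,
    average silhouette width).
    """
    X = embedding.to_numpy(dtype=float)
    n = X.shape[0]
    if not (2 <= k < n):
        raise ValueError(f"need 2 <= k < n_TFs (k={k}, n={n})")
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    rng = np.random.default_rng(seed)
    if metric == "euclidean":
        km = KMeans(n_clusters=k, n_init=n_init,
                    random_state=int(rng.integers(2**31)))
        labels = km.fit_predict(X)
        sil = silhouette_score(X, labels, metric="euclidean")
    elif metric == "manhattan":
        labels = _kmedians(X, k, rng, n_init)
        sil = silhouette_score(X, labels, metric="manhattan")
    else:
        D = (precomputed_distance if precomputed_distance is not None
             else _corr_distance(X, metric))
        labels = _kmedoids(D, k, rng, n_init)
        sil = silhouette_score(D, labels, metric="precomputed")
    assignment = pd.Series(labels + 1, index=embedding.index, name="wave")
    return assignment, float(sil)


def select_clustering(embedding: pd.DataFrame,
                      metrics: tuple[str, ...] = METRICS,
                      k_range: range = range(2, 13),
                      seed: int = 0, n_init: int = 20,
                      n_pcs: int | None = None,
                      variance_explained: np.ndarray | None = None,
                      ) -> WaveModel:
    """Evaluate the full (metric, k) grid; return the argmax of average
    silhouette width. Ties break toward smaller k, then metric order."""
    ks = [k for k in k_range]
    if not ks or not metrics:
        raise ValueError("empty (metric, k) grid")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(metrics) * len(ks))
    table = pd.DataFrame(np.nan, index=list(metrics), columns=ks)
    best = None  # (sil, k_pos, metric_pos, assignment)
    X = embedding.to_numpy(dtype=float)
    for mi, metric in enumerate(metrics):
        D = (_corr_distance(X, metric)
             if metric not in ("euclidean", "manhattan") else None)
        for ki, k in enumerate(ks):
            child_seed = int(children[mi * len(ks) + ki].generate_state(1)[0]
                             % (2**31))
            assignment, sil = cluster_with_metric(embedding, metric, k,
                                                  seed=child_seed,
                                                  n_init=n_init,
                                                  precomputed_distance=D)
            table.loc[metric, k] = sil
            key = (-sil, k, mi)
            if best is None or key < best[0]:
                best = (key, metric, k, assignment)
    _, metric, k, assignment = best
    return WaveModel(
        n_pcs=n_pcs if n_pcs is not None else embedding.shape[1],
        variance_explained=(variance_explained
                            if variance_explained is not None
                            else np.array([])),
        metric=metric, k=k, assignment=assignment, silhouette_table=table)


def fit_waves(znorm_scores: pd.DataFrame, n_pcs: int = 10,
              metrics: tuple[str, ...] = METRICS,
              k_range: range = range(2, 13), seed: int = 0,
              n_init: int = 20) -> WaveModel:
    """PCA + grid clustering + silhouette model selection in one call."""
    n_pcs = min(n_pcs, min(znorm_scores.shape) )
    emb, var = pca_embed(znorm_scores, n_pcs=n_pcs)
    return select_clustering(emb, metrics=metrics, k_range=k_range,
                             seed=seed, n_init=n_init, n_pcs=n_pcs,
                             variance_explained=np.cumsum(var))
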