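"""Isomap embedding, k-means partitions, silhouette, and partition agreement.

The symmetrised transfer-distance matrix is embedded in two dimensions with
Isomap (a 1-nearest-neighbour graph on the precomputed distances, geodesics
by shortest paths, then classical MDS).  A 1-NN graph is frequently
disconnected; rather than raising the neighbour count globally, the minimum
cross-component distance edges are added until the graph is connected, which
stays closest to the stated neighbourhood size while guaranteeing an
embedding.  Participants are then partitioned with k-means for k = 2..6,
each partition is scored with the mean silhouette coefficient
``s = (b - a) / max(a, b)`` (a: mean within-cluster distance, b: mean
distance to the nearest other cluster), and partitions from different
distance constructions are compared with the adjusted Rand index.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .exceptions import (
    DimensionError,
    EmptyDatasetError,
    ParameterError,
    ValidationError,
)

logger = logging.getLogger("swblab")

__all__ = [
    "Embedding",
    "Partition",
    "isomap_embed",
    "kmeans_partition",
    "silhouette",
    "adjusted_rand",
    "consistency_table",
    "cluster_distance_matrix",
]


@dataclass
class Embedding:
    ids: list[str]
    coords: np.ndarray  # (n, n_components)
    n_neighbors: int
    connectivity_repair: bool


@dataclass
class Partition:
    ids: list[str]
    k: int
    labels: np.ndarray
    silhouette_mean: float
    silhouette_per_sample: np.ndarray


def _knn_graph(D: np.ndarray, n_neighbors: int) -> np.ndarray:
    """Symmetric k-NN graph as a dense adjacency of distances (0 = no edge)."""
    n = D.shape[0]
    adj = np.zeros_like(D)
    order = np.argsort(D + np.diag(np.full(n, np.inf)), axis=1, kind="stable")
    for i in range(n):
        for j in order[i, :n_neighbors]:
            adj[i, j] = adj[j, i] = D[i, j]
    return adj


def _repair_connectivity(adj: np.ndarray, D: np.ndarray) -> bool:
    """Bridge disconnected components with minimum-distance edges (in place)."""
    repaired = False
    while True:
        n_comp, labels = connected_components(csr_matrix(adj), directed=False)
        if n_comp == 1:
            return repaired
        repaired = True
        best = (np.inf, -1, -1)
        for i in range(adj.shape[0]):
            for j in range(i + 1, adj.shape[0]):
                if labels[i] != labels[j] and D[i, j] < best[0]:
                    best = (D[i, j], i, j)
        _, i, j = best
        adj[i, j] = adj[j, i] = max(D[i, j], np.finfo(float).tiny)
        logger.info("isomap: bridged disconnected components with edge (%d, %d)", i, j)


def isomap_embed(
    D_sym: np.ndarray,
    n_neighbors: int = 1,
    n_components: int = 2,
    ids: list[str] | None = None,
) -> Embedding:
    """Isomap on a precomputed symmetric distance matrix.

    Builds the symmetric ``n_neighbors``-NN graph, repairs connectivity with
    minimal bridging edges if needed, computes geodesics as all-pairs
    shortest paths, and embeds with classical MDS (eigendecomposition of the
    double-centred squared-geodesic matrix).  Eigenvalue/eigenvector signs
    are fixed so the embedding is deterministic up to the usual rigid-motion
    ambiguity of MDS.
    """
    D = np.asarray(D_sym, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise DimensionError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0):
        raise ValidationError("distance matrix must have a zero diagonal")
    if n < 4:
        raise EmptyDatasetError("need at least 4 points to embed")
    if n_neighbors < 1 or n_neighbors >= n:
        raise ParameterError("n_neighbors must be in 1..n-1")
    adj = _knn_graph(D, n_neighbors)
    repaired = _repair_connectivity(adj, D)
    G = shortest_path(csr_matrix(adj), method="D", directed=False)
    # classical MDS on geodesics
    G2 = G**2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ G2 @ J
    eigval, eigvec = np.linalg.eigh(B)
    top = np.argsort(eigval)[::-1][:n_components]
    lam = np.clip(eigval[top], 0.0, None)
    coords = eigvec[:, top] * np.sqrt(lam)[None, :]
    # deterministic sign: largest-magnitude coordinate positive per axis
    for c in range(coords.shape[1]):
        col = coords[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, c] = -col
    return Embedding(
        ids=list(ids) if ids is not None else [str(i) for i in range(n)],
        coords=coords,
        n_neighbors=n_neighbors,
        connectivity_repair=repaired,
    )


def kmeans_partition(
    coords: np.ndarray, k: int, restarts: int = 50, seed: int = 0
) -> np.ndarray:
    """Best-of-``restarts`` k-means++ labels; deterministic under a fixed seed."""
    coords = np.asarray(coords, dtype=float)
    if k > coords.shape[0]:
        raise ParameterError("k must not exceed the number of points")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    return km.fit_predict(coords)


def silhouette(
    X: np.ndarray, labels: np.ndarray, precomputed: bool = False
) -> tuple[float, np.ndarray]:
    """Mean and per-sample silhouette ``s = (b - a) / max(a, b)``.

    ``a`` is the mean distance to all other points of the same cluster and
    ``b`` the mean distance to the points of the nearest other cluster.
    Samples in singleton clusters score 0 by convention; ``a = b = 0``
    scores 0.  ``X`` is either a coordinate array or, with
    ``precomputed=True``, a distance matrix.
    """
    labels = np.asarray(labels)
    D = np.asarray(X, dtype=float) if precomputed else cdist(X, X)
    if D.shape[0] != len(labels):
        raise DimensionError("labels do not match the number of samples")
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValidationError("silhouette needs at least 2 clusters")
    n = len(labels)
    s = np.zeros(n)
    for i in range(n):
        same = labels == labels[i]
        n_same = same.sum()
        if n_same == 1:
            s[i] = 0.0
            continue
        a = D[i, same].sum() / (n_same - 1)
        b = min(D[i, labels == c].mean() for c in clusters if c != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean()), s


def adjusted_rand(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Chance-adjusted Rand agreement between two partitions of the same items."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise DimensionError("partitions label different numbers of items")
    return float(adjusted_rand_score(labels_a, labels_b))


def cluster_distance_matrix(
    D_sym: np.ndarray,
    ids: list[str] | None = None,
    ks: tuple[int, ...] = (2, 3, 4, 5, 6),
    n_neighbors: int = 1,
    n_components: int = 2,
    restarts: int = 50,
    seed: int = 0,
) -> tuple[Embedding, dict[int, Partition]]:
    """Embed a distance matrix and partition it for every candidate k."""
    emb = isomap_embed(D_sym, n_neighbors=n_neighbors, n_components=n_components, ids=ids)
    partitions: dict[int, Partition] = {}
    for k in ks:
        labels = kmeans_partition(emb.coords, k, restarts=restarts, seed=seed)
        mean_s, per_s = silhouette(emb.coords, labels)
        partitions[k] = Partition(emb.ids, k, labels, mean_s, per_s)
    return emb, partitions


def consistency_table(
    partitions_by_method: dict[str, dict[int, Partition]],
    ks: tuple[int, ...] = (2, 3, 4, 5, 6),
) -> pd.DataFrame:
    """Pairwise adjusted Rand indices between methods, one row per k.

    All methods must have partitioned the same participant set.
    """
    methods = list(partitions_by_method)
    if len(methods) < 2:
        raise ValidationError("need at least 2 methods to compare")
    id_sets = {m: tuple(next(iter(p.values())).ids) for m, p in partitions_by_method.items()}
    ref = id_sets[methods[0]]
    if any(ids != ref for ids in id_sets.values()):
        raise ValidationError("methods partition different participant sets")
    rows = []
    for m1, m2 in itertools.combinations(methods, 2):
        for k in ks:
            ari = adjusted_rand(
                partitions_by_method[m1][k].labels, partitions_by_method[m2][k].labels
            )
            rows.append((f"{m1}_vs_{m2}", k, ari))
    return pd.DataFrame(rows, columns=["method_pair", "k", "ari"])
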