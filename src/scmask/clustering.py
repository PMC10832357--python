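"""Cluster cell embeddings: K-means for small datasets, Leiden for large.

The method switch is a plain cell-count threshold: K-means below 10 000
cells, Leiden community detection on a kNN graph at or above it. Leiden has
no direct "number of clusters" knob, so the resolution parameter is driven
to the requested k by bisection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

METHOD_SWITCH_CELLS = 10_000


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    method: str  # "kmeans" | "leiden"
    n_clusters_requested: int
    params: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def n_clusters_found(self) -> int:
        return int(len(np.unique(self.labels)))

    def to_frame(self, cell_ids: list[str] | None = None) -> pd.DataFrame:
        ids = cell_ids if cell_ids is not None else [str(i) for i in range(len(self.labels))]
        return pd.DataFrame({"cell_id": ids, "cluster": self.labels})

    def write(self, path, cell_ids: list[str] | None = None) -> None:
        self.to_frame(cell_ids).to_csv(path, sep="\t", index=False)


def choose_method(c: int) -> str:
    """K-means strictly below the 10 000-cell threshold, Leiden otherwise."""
    if c < 2:
        raise ValueError("need at least 2 cells to cluster")
    return "kmeans" if c < METHOD_SWITCH_CELLS else "leiden"


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel to 0..K-1 by descending cluster size (ties by old label)."""
    uniq, counts = np.unique(labels, return_counts=True)
    order = sorted(range(len(uniq)), key=lambda i: (-counts[i], uniq[i]))
    mapping = {uniq[i]: rank for rank, i in enumerate(order)}
    return np.array([mapping[l] for l in labels], dtype=np.int64)


def cluster_kmeans(
    e: np.ndarray, k: int, seed: int = 0, restarts: int = 20
) -> ClusterAssignment:
    """Best-of-``restarts`` Lloyd K-means on the embedding."""
    e = np.asarray(e, dtype=np.float64)
    if k > e.shape[0]:
        raise ValueError(f"k={k} exceeds the number of cells ({e.shape[0]})")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = _relabel_by_size(km.fit_predict(e))
    return ClusterAssignment(
        labels=labels,
        method="kmeans",
        n_clusters_requested=k,
        params={"restarts": restarts, "inertia": float(km.inertia_)},
        seed=seed,
    )


def _knn_graph(e: np.ndarray, knn: int) -> ig.Graph:
    """Undirected union of Euclidean kNN edges (no self loops)."""
    nn = NearestNeighbors(n_neighbors=knn + 1).fit(e)
    _, idx = nn.kneighbors(e)
    edges = set()
    for i, row in enumerate(idx):
        for j in row:
            if j != i:
                edges.add((min(i, int(j)), max(i, int(j))))
    return ig.Graph(n=e.shape[0], edges=sorted(edges))


def cluster_leiden(
    e: np.ndarray,
    k_target: int,
    seed: int = 0,
    knn: int = 15,
    max_iter: int = 30,
) -> ClusterAssignment:
    """Leiden modularity clustering on a kNN graph, resolution tuned to k.

    Bisection over the resolution parameter in [1e-3, 10] until the number
    of communities matches ``k_target``; if unattainable within ``max_iter``
    evaluations, the closest achieved partition is returned and the achieved
    count recorded in ``params``. Disconnected graphs are fine: Leiden
    clusters each component independently.
    """
    e = np.asarray(e, dtype=np.float64)
    c = e.shape[0]
    if knn >= c:
        raise ValueError(f"knn={knn} must be smaller than the number of cells ({c})")
    graph = _knn_graph(e, knn)

    def run(res: float):
        part = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=res,
            seed=seed,
        )
        return np.asarray(part.membership, dtype=np.int64)

    lo, hi = 1e-3, 10.0
    best_labels, best_res, best_gap = None, None, np.inf

    def consider(res: float) -> int:
        nonlocal best_labels, best_res, best_gap
        labels = run(res)
        k = len(np.unique(labels))
        gap = abs(k - k_target)
        if gap < best_gap:
            best_labels, best_res, best_gap = labels, res, gap
        return k

    k_lo = consider(lo)
    k_hi = consider(hi)
    if k_lo < k_target < k_hi:
        for _ in range(max_iter):
            if best_gap == 0:
                break
            mid = 0.5 * (lo + hi)
            k_mid = consider(mid)
            if k_mid < k_target:
                lo = mid
            else:
                hi = mid
    labels = _relabel_by_size(best_labels)
    return ClusterAssignment(
        labels=labels,
        method="leiden",
        n_clusters_requested=k_target,
        params={
            "knn": knn,
            "resolution": float(best_res),
            "n_clusters_achieved": int(len(np.unique(labels))),
        },
        seed=seed,
    )


def cluster(
    e: np.ndarray,
    k: int,
    seed: int = 0,
    restarts: int = 20,
    knn: int = 15,
) -> ClusterAssignment:
    """Dispatch to K-means or Leiden based on :func:`choose_method`."""
    if choose_method(e.shape[0]) == "kmeans":
        return cluster_kmeans(e, k, seed=seed, restarts=restarts)
    return cluster_leiden(e, k, seed=seed, knn=knn)
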