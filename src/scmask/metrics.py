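"""Clustering evaluation: ARI, NMI, and silhouette-based embedding scores.

ARI and NMI compare a predicted partition with reference labels. The two
silhouette scores act on the embedding itself: the cell-type score rescales
the average silhouette width (ASW in [-1, 1]) to [0, 1] via (ASW + 1) / 2,
so larger means denser, better-separated cell types; the batch score
inverts it, 1 - |ASW|, so 1 means batches are perfectly mixed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import (
    adjusted_rand_score,
    normalized_mutual_info_score,
    silhouette_score,
)


def _check_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape:
        raise ValueError(f"label vectors differ in length: {a.size} vs {b.size}")
    return a, b


def adjusted_rand_index(a, b) -> float:
    """Pair-counting partition agreement, chance-corrected; 1 = identical."""
    a, b = _check_pair(a, b)
    if a.size < 2:
        raise ValueError("need at least 2 cells")
    return float(adjusted_rand_score(a, b))


def normalized_mutual_info(a, b, average_method: str = "arithmetic") -> float:
    """Mutual information normalized by the (by default arithmetic) mean of
    the two label entropies.

    Degenerate single-cluster-on-both-sides input is defined as 1.0 (the two
    trivial partitions are identical); single-cluster on one side only gives
    0.0.
    """
    a, b = _check_pair(a, b)
    n_a, n_b = len(np.unique(a)), len(np.unique(b))
    if n_a == 1 and n_b == 1:
        return 1.0
    if n_a == 1 or n_b == 1:
        return 0.0
    return float(normalized_mutual_info_score(a, b, average_method=average_method))


def cell_type_asw(e: np.ndarray, labels) -> float:
    """Euclidean silhouette of the labeling on the embedding, mapped to
    [0, 1] by (ASW + 1) / 2."""
    e = np.asarray(e, dtype=np.float64)
    labels = np.asarray(labels).ravel()
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette needs at least 2 distinct labels")
    asw = silhouette_score(e, labels, metric="euclidean")
    return float((asw + 1.0) / 2.0)


def batch_asw(e: np.ndarray, batch_labels) -> float:
    """Batch-mixing score 1 - |ASW(batch)|; 1 = perfectly mixed batches."""
    e = np.asarray(e, dtype=np.float64)
    batch_labels = np.asarray(batch_labels).ravel()
    if len(np.unique(batch_labels)) < 2:
        raise ValueError("batch silhouette needs at least 2 batches")
    asw = silhouette_score(e, batch_labels, metric="euclidean")
    return float(1.0 - abs(asw))


@dataclass
class MetricsReport:
    ari: float
    nmi: float
    cell_type_asw: float
    n_clusters_found: int
    batch_asw: float | None = None
    seed: int | None = None
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "ari": self.ari,
            "nmi": self.nmi,
            "cell_type_asw": self.cell_type_asw,
            "n_clusters_found": self.n_clusters_found,
        }
        if self.batch_asw is not None:
            out["batch_asw"] = self.batch_asw
        if self.seed is not None:
            out["seed"] = self.seed
        if self.config:
            out["config"] = self.config
        return out

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def summary(self) -> str:
        parts = [
            f"ARI={self.ari:.4f}",
            f"NMI={self.nmi:.4f}",
            f"cell-type ASW={self.cell_type_asw:.4f}",
        ]
        if self.batch_asw is not None:
            parts.append(f"batch ASW={self.batch_asw:.4f}")
        parts.append(f"clusters={self.n_clusters_found}")
        return " ".join(parts)


def evaluate(
    e: np.ndarray,
    pred_labels,
    true_labels,
    batch_labels=None,
    seed: int | None = None,
    config: dict | None = None,
) -> MetricsReport:
    """Full report: ARI/NMI of prediction vs truth, cell-type ASW of the
    true labels on the embedding, and batch ASW when batch labels exist."""
    pred, true = _check_pair(pred_labels, true_labels)
    return MetricsReport(
        ari=adjusted_rand_index(true, pred),
        nmi=normalized_mutual_info(true, pred),
        cell_type_asw=cell_type_asw(e, true),
        n_clusters_found=int(len(np.unique(pred))),
        batch_asw=None if batch_labels is None else batch_asw(e, batch_labels),
        seed=seed,
        config=config or {},
    )
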