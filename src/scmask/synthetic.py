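"""Cluster-structured scRNA-seq count simulator with ground-truth labels.

Counts follow a negative binomial with mean mu and dispersion theta
(variance mu + mu^2 / theta), sampled as a gamma-Poisson mixture. Cluster
identity enters through disjoint blocks of marker genes up-regulated on the
natural-log scale; optional batch structure adds a per-batch per-gene
log-normal multiplicative factor. Zeros are additionally inflated by a
dropout whose probability is logistic in the log-mean, reproducing the
mean-dependent sparsity of real droplet data.

The default specification is the study condition used throughout the test
suite: 1000 cells x 500 genes, five clusters at proportions
(0.30, 0.30, 0.20, 0.19, 0.01) — one of them deliberately small — with 20
markers per cluster at log-fold-change 1.5. :func:`rare_type_scenario`
provides a harder preset with two truly rare populations (0.4% and 0.3%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix

DEFAULT_PROPORTIONS = (0.30, 0.30, 0.20, 0.19, 0.01)


@dataclass
class SyntheticSpec:
    n_cells: int = 1000
    n_genes: int = 500
    n_clusters: int = 5
    cluster_proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    n_marker_genes_per_cluster: int = 20
    marker_log_fold_change: float = 1.5
    base_mean_log_range: tuple[float, float] = (-1.0, 1.5)
    nb_dispersion: float = 2.0
    dropout_midpoint: float = 0.0
    dropout_slope: float = 1.0
    n_batches: int = 1
    batch_effect_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.cluster_proportions, dtype=np.float64)
        if len(p) != self.n_clusters:
            raise ValueError(
                f"{len(p)} proportions given for {self.n_clusters} clusters"
            )
        if np.any(p <= 0):
            raise ValueError("cluster proportions must be positive")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"cluster proportions sum to {p.sum()}, not 1")
        if self.n_marker_genes_per_cluster * self.n_clusters > self.n_genes:
            raise ValueError("marker blocks exceed the number of genes")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.batch_effect_sd < 0:
            raise ValueError("batch_effect_sd must be non-negative")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        if self.n_cells * p.min() < 2:
            raise ValueError(
                "infeasible spec: smallest cluster expects fewer than 2 cells"
            )


def _substreams(seed: int):
    names = ("assign", "base", "batch", "counts", "dropout")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _base_and_markers(spec: SyntheticSpec, base_rng: np.random.Generator):
    lo, hi = spec.base_mean_log_range
    base = base_rng.uniform(lo, hi, size=spec.n_genes)
    log_means = np.tile(base, (spec.n_clusters, 1))
    m = spec.n_marker_genes_per_cluster
    for k in range(spec.n_clusters):
        log_means[k, k * m : (k + 1) * m] += spec.marker_log_fold_change
    return log_means


def latent_means(spec: SyntheticSpec) -> np.ndarray:
    """Per-cluster latent mean matrix (K x G), before batch effects and
    sampling; uses the same random substream as :func:`simulate_counts`."""
    rngs = _substreams(spec.seed)
    return np.exp(_base_and_markers(spec, rngs["base"]))


def simulate_counts(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, np.ndarray, np.ndarray]:
    """Draw one dataset; returns (counts, cluster labels, batch labels).

    Reproducible: a given spec (including its seed) always yields the same
    matrix. Cluster sizes are multinomial with a floor of 2 cells per
    cluster (deficits are taken from the largest cluster).
    """
    rngs = _substreams(spec.seed)
    p = np.asarray(spec.cluster_proportions, dtype=np.float64)

    sizes = rngs["assign"].multinomial(spec.n_cells, p)
    while sizes.min() < 2:  # feasibility guard for tiny rare clusters
        sizes[np.argmax(sizes)] -= 1
        sizes[np.argmin(sizes)] += 1
    labels = np.repeat(np.arange(spec.n_clusters), sizes)
    labels = labels[rngs["assign"].permutation(spec.n_cells)]
    batches = rngs["assign"].integers(0, spec.n_batches, size=spec.n_cells)

    log_means = _base_and_markers(spec, rngs["base"])  # K x G
    batch_shift = np.zeros((spec.n_batches, spec.n_genes))
    if spec.n_batches > 1 and spec.batch_effect_sd > 0:
        batch_shift = rngs["batch"].normal(
            0.0, spec.batch_effect_sd, size=(spec.n_batches, spec.n_genes)
        )

    log_mu = log_means[labels] + batch_shift[batches]  # C x G
    mu = np.exp(log_mu)
    theta = spec.nb_dispersion
    lam = rngs["counts"].gamma(shape=theta, scale=mu / theta)
    counts = rngs["counts"].poisson(lam).astype(np.float64)

    # mean-dependent dropout: low-expression entries are more likely zeroed
    p_drop = 1.0 / (1.0 + np.exp(spec.dropout_slope * (log_mu - spec.dropout_midpoint)))
    counts *= rngs["dropout"].random(counts.shape) >= p_drop

    width = len(str(max(spec.n_cells, spec.n_genes)))
    em = ExpressionMatrix(
        values=counts,
        cell_ids=[f"cell_{i:0{width}d}" for i in range(spec.n_cells)],
        gene_ids=[f"gene_{j:0{width}d}" for j in range(spec.n_genes)],
        stage="raw_counts",
    )
    return em, labels, batches


def rare_type_scenario(seed: int = 0) -> tuple[ExpressionMatrix, np.ndarray]:
    """Preset stressing rare-population detection: 6000 cells, 8 clusters,
    two of them at 0.4% and 0.3% frequency with strong markers (lfc=2.5)."""
    rare = (0.004, 0.003)
    common = (1.0 - sum(rare)) / 6
    spec = SyntheticSpec(
        n_cells=6000,
        n_genes=800,
        n_clusters=8,
        cluster_proportions=tuple([common] * 6 + list(rare)),
        n_marker_genes_per_cluster=25,
        marker_log_fold_change=2.5,
        seed=seed,
    )
    em, labels, _ = simulate_counts(spec)
    return em, labels
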