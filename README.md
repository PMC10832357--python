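# scmask

Masked-autoencoder cell embeddings for single-cell RNA-seq clustering.

Unsupervised clustering of cells is the workhorse of scRNA-seq analysis,
and its quality hinges on the low-dimensional representation the clusters
are cut from. `scmask` learns that representation with a self-supervised
*masked autoencoder*: part of the expression matrix is corrupted by
**per-gene shuffling** — a masked entry is replaced by the same gene's
value from another random cell, so every gene's marginal distribution is
preserved — and the network is trained both to **detect** which entries
were corrupted and to **reconstruct** the original values. Solving either
task requires modelling the dependencies *between* genes, which is exactly
what makes the resulting cell embeddings informative for clustering,
including for rare cell populations.

## Model

Given the processed matrix X ∈ R^{C×G}, a Bernoulli mask M (per-gene
probabilities p_j, default 0.3) and the column-shuffled matrix X′ define
the corrupted input

    XM = X ⊙ (1 − M) + X′ ⊙ M.

An MLP encoder (256 → 64 → linear 32) maps XM to embeddings E; a linear
head predicts the mask, M̃ = σ(E W_m + b_m), and a linear decoder
reconstructs X from the concatenation [E, M̃]. Training minimizes

    L = (1 − γ)·mean[Ω ⊙ (X − X̃)²] + γ·BCE(M, M̃),
    Ω = M λ + (1 − M)(1 − λ),

with λ = 0.75 (emphasis on corrupted entries) and γ = 0.5. Embeddings of
the clean matrix are clustered with K-means below 10 000 cells and Leiden
(kNN graph, resolution bisected to the requested k) above. Ablation modes
reconstruct only the unmasked portion, only the masked portion, or drop the
mask-estimation loss. Gradients are analytic NumPy (finite-difference
verified); everything is exactly reproducible from one seed.

See `docs/methods.md` for assumptions, parameter meanings, and limitations.

## Worked example

```python
import scmask

spec = scmask.SyntheticSpec(
    n_cells=300, n_genes=120, n_clusters=3,
    cluster_proportions=(0.5, 0.3, 0.2),
    n_marker_genes_per_cluster=15, seed=0,
)
counts, labels, _ = scmask.simulate_counts(spec)       # NB counts + truth
x = scmask.preprocess(counts, n_hvg=100)               # normalize/log/HVG/scale
state, trace = scmask.train(x, scmask.TrainConfig(epochs=100, seed=0))
emb = scmask.embed(state, x)                           # 300 x 32, clean input
assign = scmask.cluster(emb, k=3, seed=0)              # k-means (C < 10000)
report = scmask.evaluate(emb, assign.labels, labels)
print(f"final loss {trace.total[-1]:.4f} "
      f"(recon {trace.recon[-1]:.4f}, mask {trace.mask[-1]:.4f})")
print(report.summary())
```

prints

```
final loss 0.4762 (recon 0.3354, mask 0.6171)
ARI=0.9900 NMI=0.9821 cell-type ASW=0.6876 clusters=3
```

ARI/NMI near 1 mean the three simulated populations were recovered almost
exactly; the cell-type ASW of 0.69 (on a 0–1 scale, 0.5 = overlapping)
reflects moderately compact, separated clusters in the embedding. The mask
term settling near ln 2 ≈ 0.61–0.69 is expected on this generator — see the
methods note on what is detectable under conditionally independent genes.

The same pipeline runs from the shell on 10x triplet directories, delimited
text, or `.h5ad` files:

```sh
scmask --input counts.csv --format csv --n-clusters 3 \
       --labels labels.tsv --seed 0 --out runs/demo
```

writing the embedding, cluster assignments, training trace, metrics JSON,
model checkpoint, resolved config, and a log into `runs/demo/`.

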