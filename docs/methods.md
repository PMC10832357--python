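# Methods

## Model

`scmask` learns cell embeddings for single-cell RNA-seq clustering by
self-supervision on a corrupted expression matrix. Let X ∈ R^{C×G} be the
processed (library-normalized, log1p, HVG-selected, standardized) matrix of
C cells and G genes.

**Corruption.** Each gene's column is independently permuted across cells to
give X′, and a Bernoulli mask M with per-gene probabilities p_j (default
p_j = 0.3 for all genes) selects which entries are replaced:

    XM_ij = X_ij (1 − M_ij) + X′_ij M_ij.

Because a corrupted entry is another cell's value for the *same* gene, the
corruption preserves every gene's marginal distribution; detecting it
requires exploiting dependencies between genes, which is exactly the signal
we want the encoder to internalize. During training, both the mask and the
permutation are redrawn for every minibatch of every epoch; a fixed
corruption could be memorized, making the mask-estimation task trivial.
Permutations are drawn within the minibatch.

**Network.** A multilayer perceptron encoder (hidden layers 256 and 64,
ReLU; final linear projection to a 32-dimensional latent space) maps XM to
embeddings E. Two linear heads share this encoder: a *mask predictor*
M̃ = σ(E W_m + b_m) estimating per-entry corruption probabilities, and a
*decoder* X̃ = [E, M̃] W_d + b_d reconstructing the clean matrix from the
embedding concatenated with the predicted mask (so the decoder knows which
entries to distrust). The concatenation order is fixed (embedding first)
and the decoder receives predicted probabilities, not thresholded labels.

**Losses.** The mask-estimation loss is the mean binary cross-entropy over
all C·G entries,

    Lm = −mean[ M log M̃ + (1 − M) log(1 − M̃) ],

with predictions clamped to [ε, 1−ε], ε = 1e−7. A single-term variant
(−mean M log M̃) is available via `positive_term_only`; it is *not* the
default because its optimum is the constant M̃ ≡ 1 — the head saturates and
stops discriminating (the loss rushes to zero without any detection skill;
see "Known limitations"). The reconstruction loss is a mask-weighted MSE,

    Lr = mean[ Ω (X − X̃)² ],   Ω = M λ + (1 − M)(1 − λ),

with λ = 0.75 by default, emphasizing corrupted entries. The training
objective is L = (1 − γ) Lr + γ Lm with γ = 0.5. Both normalizers are means
over all entries so λ and γ do not interact with batch size. Ablation
modes: `unmasked_only` (Ω = 1 − M), `masked_only` (Ω = M), and
`no_mask_loss` (L = Lr; the mask head stays in the architecture so the
decoder input is unchanged, but its parameters are frozen — gradients still
flow *through* the frozen head into the encoder, which keeps the ablation a
pure loss-term change rather than an architecture change).

**Optimization.** All parameters are plain NumPy arrays; gradients are
derived analytically and verified against central finite differences
(relative error < 1e−4 in the test suite, away from ReLU kinks where finite
differences are invalid). Adam with learning rate 1e−3, batch size 256,
300 epochs by default (200 in the evaluation runs below). Glorot-uniform
weight init, zero biases. A single seed fans out through
`numpy.random.SeedSequence.spawn` into independent substreams for
initialization, batch order, shuffling, and masking, so runs are exactly
reproducible. Non-finite losses abort with the epoch/batch index. No early
stopping by default.

**Inference.** Embeddings for clustering are the encoder output on the
*clean* matrix — corrupting at inference would inject noise into the
downstream clustering for no benefit.

## Preprocessing

The pipeline is the consensus scRNA-seq recipe: drop genes expressed in
fewer than 3 cells; per-cell library-size normalization to 1e4; log1p;
top-2000 genes by dispersion-based ranking (scanpy's `seurat` flavor);
per-gene standardization clipped to [−10, 10]. All five knobs are exposed.
Zero-variance genes standardize to all-zero columns rather than NaN. Cells
with zero total count are an error (reported by identifier). The pipeline
is deterministic.

## Clustering

K-means (best of 20 restarts) below 10 000 cells; Leiden on a Euclidean
15-nearest-neighbor graph (undirected union of directed kNN edges,
RBConfiguration modularity) at or above. The number of clusters k is
user-supplied. Leiden has no k parameter, so the resolution is driven to k
by bisection on [1e−3, 10] (≤30 evaluations); if k is unattainable the
closest partition is returned and the achieved count recorded. Labels are
renumbered by descending cluster size for determinism.

## Evaluation metrics

ARI and NMI (arithmetic-mean normalization; configurable) compare predicted
and reference partitions. Cell-type ASW is the mean Euclidean silhouette of
the reference labels on the embedding mapped to [0, 1] via (ASW + 1)/2;
batch ASW is 1 − |ASW| of the batch labels, so 1 means perfect mixing. Both
silhouettes are computed on the learned embedding. Degenerate NMI input
(one cluster on both sides) is defined as 1.0; one-sided degeneracy gives
0.0. Singleton clusters take silhouette 0.

## Synthetic data

The generator draws per-gene base means log-uniform on [−1.0, 1.5] (natural
log; mean counts ≈ 0.37–4.5, typical of droplet-level depth for variable
genes), assigns each cluster a disjoint block of marker genes up-regulated
by a log-fold-change (default 1.5 natural-log units ≈ 4.5-fold), and
samples counts from a negative binomial with mean μ and dispersion θ = 2
(variance μ + μ²/θ) via a gamma–Poisson mixture. Zeros are further inflated
by dropout with probability logistic in log μ (midpoint 0, slope 1),
reproducing mean-dependent sparsity; overall sparsity of the default
dataset is ≈ 62%. Optional batch structure multiplies means by per-batch
per-gene log-normal factors (sd configurable, 0 disables). Cluster sizes
are multinomial with a floor of two cells per cluster.

Defaults define the study conditions used by the tests and the acceptance
script: 1000 cells × 500 genes, five clusters at proportions
(0.30, 0.30, 0.20, 0.19, 0.01), 20 markers per cluster. The rare-population
preset uses 6000 cells × 800 genes, eight clusters with two at 0.4% and
0.3% frequency and stronger markers (lfc 2.5, 25 markers per cluster).

**What the generator does not emulate.** Genes are conditionally
independent given the cluster (no co-expression modules, no per-cell
library-size factors, no trajectories or cell-cycle structure). This has a
direct consequence for the mask-estimation task: a non-marker gene's values
are exchangeable across cells, so whether an entry was shuffled is
*information-theoretically undetectable* for such genes, and even for
marker genes detection is only possible when the donor cell's cluster
differs visibly from the recipient's. Real data, with its pervasive
gene–gene correlation, gives the mask predictor far more to work with.
Passing (or failing) mask-detection checks on this generator therefore
bounds what the synthetic conditions allow, not what the method achieves on
real data (see below).

## Evaluation protocol and problem sizes

The acceptance script and the end-to-end tests run the full pipeline on the
default conditions over five seeds (400 HVGs kept of the ~490 that survive
gene filtering — deliberately permissive, because aggressive dispersion
ranking preferentially discards rare-cluster markers, whose dispersion is
diluted by their 1% frequency), 200 training epochs, k-means with k = 5;
plus the rare-population preset (600 HVGs, k = 8) and a masked-only
ablation arm over the same five seeds.

Measured behavior under these conditions (recomputed by
`scripts/acceptance.py`, seed 0 base):

- The rare-population preset is solved essentially perfectly: both sub-0.5%
  clusters are recovered as pure clusters.
- On the default conditions, median ARI sits near the mid-0.8s for the full
  model and all ablation arms alike. The binding constraint is the data,
  not the representation: the 1% cluster's centroid lies closer to its
  nearest neighbor than the within-cluster radius (at θ = 2 with dropout),
  so no clustering of any embedding isolates it reliably, and k-means
  spends its fifth centroid splitting a large cluster. A PCA + k-means
  baseline lands within ±0.01 ARI of the model on the same draws.
- The ablation arms are statistically indistinguishable at this scale:
  the seed-to-seed spread of the k-means solution (±0.03 ARI) exceeds the
  effect of the loss-term changes.
- The smoothed total loss decreases monotonically. The mask-estimation
  loss, however, plateaus near the base-rate entropy h(0.3) ≈ 0.61: as
  derived above, most entries carry no mask information under this
  generator, and an explicit Bayes-ceiling computation (posterior from the
  per-gene, per-cluster value distributions, using the *true* labels) caps
  balanced accuracy at ≈ 0.54. The trained predictor's thresholded balanced
  accuracy ≈ 0.5 is consistent with that ceiling, not a training failure —
  under the single-term loss variant the same model drives Lm below 1e−3
  within tens of epochs, but only by saturating at M̃ ≡ 1.

## Known limitations

- No GPU path, learning-rate schedules, or distributed training; the NumPy
  implementation is single-threaded apart from BLAS.
- The Leiden resolution search assumes community count is monotone in
  resolution, which modularity optimization only approximately satisfies.
- HVG selection before model fitting can discard markers of very rare
  populations; the permissive defaults used in the evaluation mitigate but
  do not remove this.
- The synthetic generator's conditional independence makes mask-estimation
  checks conservative, as discussed above.
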