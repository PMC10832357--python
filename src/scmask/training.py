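"""Minibatch training loop for the masked autoencoder.

Each epoch reshuffles the cell order; each minibatch draws a *fresh*
corruption (per-gene shuffle within the batch plus a Bernoulli mask), so the
mask-prediction task cannot be solved by memorizing a fixed corruption.
Optimization is Adam. A single seed fans out into independent substreams for
parameter initialization, batch order, shuffling and masking, making runs
fully reproducible.

Embeddings for downstream clustering come from :func:`embed`, which encodes
the clean (uncorrupted) matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corruption import MaskConfig, _corrupt
from .io import ExpressionMatrix
from .model import (
    ArchitectureSpec,
    LossConfig,
    ModelState,
    encode,
    init_state,
    loss_and_grads,
    predict_mask,
)


@dataclass
class TrainConfig:
    epochs: int = 300
    batch_size: int = 256
    learning_rate: float = 1e-3
    seed: int = 0
    mask: MaskConfig = field(default_factory=MaskConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    arch: ArchitectureSpec | None = None  # input_dim filled in from the data

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class TrainingTrace:
    """Per-epoch mean losses (total, reconstruction, mask-estimation)."""

    total: np.ndarray
    recon: np.ndarray
    mask: np.ndarray

    def __len__(self) -> int:
        return len(self.total)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.total) + 1),
                "loss": self.total,
                "lr_term": self.recon,
                "lm_term": self.mask,
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


class _Adam:
    """Standard Adam updates over a named parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1**self.t)
            v_hat = self.v[k] / (1 - b2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def train(x: ExpressionMatrix, cfg: TrainConfig) -> tuple[ModelState, TrainingTrace]:
    """Train the masked autoencoder on a scaled matrix.

    Returns the final model state and the per-epoch loss trace. With
    ``epochs=0`` the freshly initialized state is returned untouched.
    """
    if x.stage != "scaled":
        raise ValueError(f"train expects a scaled matrix, got stage={x.stage!r}")
    values = x.values
    c, g = values.shape
    arch = cfg.arch if cfg.arch is not None else ArchitectureSpec(input_dim=g)
    if arch.input_dim != g:
        raise ValueError(f"architecture input_dim={arch.input_dim} but data has {g} genes")
    probs = cfg.mask.probs(g)

    init_ss, order_ss, shuf_ss, mask_ss = np.random.SeedSequence(cfg.seed).spawn(4)
    state = init_state(arch, np.random.default_rng(init_ss))
    order_rng = np.random.default_rng(order_ss)
    shuffle_rng = np.random.default_rng(shuf_ss)
    mask_rng = np.random.default_rng(mask_ss)

    opt = _Adam(state.params(), lr=cfg.learning_rate)
    totals, recons, masks = [], [], []
    for epoch in range(cfg.epochs):
        perm = order_rng.permutation(c)
        ep_tot = ep_lr = ep_lm = 0.0
        for start in range(0, c, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            xb = values[idx]
            art = _corrupt(xb, probs, shuffle_rng, mask_rng)
            tot, lr_term, lm_term, grads = loss_and_grads(
                state, xb, art.corrupted, art.mask, cfg.loss
            )
            if not np.isfinite(tot):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {start // cfg.batch_size}"
                )
            opt.step(grads)
            w = len(idx)
            ep_tot += tot * w
            ep_lr += lr_term * w
            ep_lm += lm_term * w
        totals.append(ep_tot / c)
        recons.append(ep_lr / c)
        masks.append(ep_lm / c)
    trace = TrainingTrace(
        total=np.array(totals), recon=np.array(recons), mask=np.array(masks)
    )
    return state, trace


def embed(state: ModelState, x: ExpressionMatrix) -> np.ndarray:
    """Encode the clean (uncorrupted) matrix into cell embeddings.

    No corruption is applied at inference; deterministic for a fixed state.
    """
    if x.stage != "scaled":
        raise ValueError(f"embed expects a scaled matrix, got stage={x.stage!r}")
    return encode(state, x.values)


def mask_predictor_balanced_accuracy(
    state: ModelState,
    x: ExpressionMatrix,
    mask_cfg: MaskConfig,
    seed: int,
    n_draws: int = 5,
) -> float:
    """Balanced accuracy of the thresholded mask predictor on fresh draws.

    For each draw, corrupt the full matrix with a new seed, encode the
    corrupted matrix, threshold the predicted mask at 0.5, and score against
    the true mask as (TPR + TNR) / 2; returns the mean over draws.
    """
    if x.stage != "scaled":
        raise ValueError("expects a scaled matrix")
    probs = mask_cfg.probs(x.n_genes)
    shuf_ss, mask_ss = np.random.SeedSequence(seed).spawn(2)
    shuffle_rng = np.random.default_rng(shuf_ss)
    mask_rng = np.random.default_rng(mask_ss)
    scores = []
    for _ in range(n_draws):
        art = _corrupt(x.values, probs, shuffle_rng, mask_rng)
        m_pred = predict_mask(state, encode(state, art.corrupted)) >= 0.5
        m_true = art.mask.astype(bool)
        tpr = m_pred[m_true].mean() if m_true.any() else np.nan
        tnr = (~m_pred[~m_true]).mean() if (~m_true).any() else np.nan
        scores.append(0.5 * (tpr + tnr))
    return float(np.mean(scores))
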