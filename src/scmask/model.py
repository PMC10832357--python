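"""Masked autoencoder: encoder, mask predictor, decoder, and the losses.

The network sees the corrupted matrix XM and is trained on two coupled
pretext tasks that share the encoder:

* a linear *mask predictor* estimating, per entry, whether it was corrupted
  (binary cross-entropy loss Lm), and
* a linear *decoder* reconstructing the clean matrix X from the embedding
  concatenated with the predicted mask, under a mask-weighted MSE

      Lr = (1/N) sum_ij Omega_ij (X_ij - Xhat_ij)^2,
      Omega_ij = M_ij * lambda + (1 - M_ij) * (1 - lambda),

  so lambda > 1/2 emphasises the corrupted entries.

The total objective is L = (1 - gamma) * Lr + gamma * Lm. Ablation modes:
``unmasked_only`` (Omega = 1 - M), ``masked_only`` (Omega = M) and
``no_mask_loss`` (L = Lr; mask head present but frozen).

Parameters are plain NumPy arrays; gradients are computed analytically in
:func:`loss_and_grads` (verified against central finite differences in the
test suite).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

ABLATIONS = ("full", "unmasked_only", "masked_only", "no_mask_loss")
ACTIVATIONS = ("relu", "elu")


@dataclass
class ArchitectureSpec:
    input_dim: int
    hidden_dims: list[int] = field(default_factory=lambda: [256, 64])
    latent_dim: int = 32
    activation: str = "relu"

    def __post_init__(self) -> None:
        self.hidden_dims = [int(h) for h in self.hidden_dims]
        if not self.hidden_dims:
            raise ValueError("hidden_dims must be non-empty")
        if any(h < 1 for h in self.hidden_dims):
            raise ValueError("hidden layer sizes must be positive")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be positive")
        if self.latent_dim >= self.input_dim:
            raise ValueError(
                f"latent_dim ({self.latent_dim}) must be smaller than "
                f"input_dim ({self.input_dim})"
            )
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation must be one of {ACTIVATIONS}")


@dataclass
class LossConfig:
    lambda_mask_weight: float = 0.75
    gamma_balance: float = 0.5
    ablation: str = "full"
    positive_term_only: bool = False  # printed single-term cross-entropy variant
    eps: float = 1e-7

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_mask_weight <= 1.0:
            raise ValueError("lambda_mask_weight must lie in [0, 1]")
        if not 0.0 <= self.gamma_balance <= 1.0:
            raise ValueError("gamma_balance must lie in [0, 1]")
        if self.ablation not in ABLATIONS:
            raise ValueError(f"ablation must be one of {ABLATIONS}")


@dataclass
class ModelState:
    """All learnable parameters plus the architecture that shaped them.

    ``enc_W[l]`` / ``enc_b[l]`` cover the hidden layers and the final linear
    projection to the latent space; the mask predictor and decoder are single
    affine maps (latent -> G and latent+G -> G respectively).
    """

    arch: ArchitectureSpec
    enc_W: list[np.ndarray]
    enc_b: list[np.ndarray]
    mask_W: np.ndarray
    mask_b: np.ndarray
    dec_W: np.ndarray
    dec_b: np.ndarray

    def params(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, (w, b) in enumerate(zip(self.enc_W, self.enc_b)):
            out[f"enc_W{i}"] = w
            out[f"enc_b{i}"] = b
        out["mask_W"] = self.mask_W
        out["mask_b"] = self.mask_b
        out["dec_W"] = self.dec_W
        out["dec_b"] = self.dec_b
        return out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_state(arch: ArchitectureSpec, rng: np.random.Generator) -> ModelState:
    dims = [arch.input_dim, *arch.hidden_dims, arch.latent_dim]
    enc_W = [_glorot(rng, dims[i], dims[i + 1]) for i in range(len(dims) - 1)]
    enc_b = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
    g, d = arch.input_dim, arch.latent_dim
    return ModelState(
        arch=arch,
        enc_W=enc_W,
        enc_b=enc_b,
        mask_W=_glorot(rng, d, g),
        mask_b=np.zeros(g),
        dec_W=_glorot(rng, d + g, g),
        dec_b=np.zeros(g),
    )


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(z, 0.0)
    return np.where(z > 0, z, np.expm1(z))  # elu


def _act_grad(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return (z > 0).astype(np.float64)
    return np.where(z > 0, 1.0, np.exp(z))


def _encode_cache(state: ModelState, xm: np.ndarray):
    """Forward through the encoder keeping pre-activations for backprop."""
    h = np.asarray(xm, dtype=np.float64)
    if h.shape[1] != state.arch.input_dim:
        raise ValueError(
            f"input has {h.shape[1]} columns, encoder expects {state.arch.input_dim}"
        )
    inputs, preacts = [], []
    n_hidden = len(state.enc_W) - 1
    for l in range(n_hidden):
        inputs.append(h)
        z = h @ state.enc_W[l] + state.enc_b[l]
        preacts.append(z)
        h = _act(z, state.arch.activation)
        if not np.all(np.isfinite(h)):
            raise FloatingPointError(f"non-finite activations in encoder layer {l}")
    inputs.append(h)
    e = h @ state.enc_W[-1] + state.enc_b[-1]  # final layer is linear
    if not np.all(np.isfinite(e)):
        raise FloatingPointError(f"non-finite activations in encoder layer {n_hidden}")
    return e, inputs, preacts


def encode(state: ModelState, xm: np.ndarray) -> np.ndarray:
    """Map (possibly corrupted) expression to the latent embedding E."""
    e, _, _ = _encode_cache(state, xm)
    return e


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def predict_mask(state: ModelState, e: np.ndarray) -> np.ndarray:
    """Per-entry corruption probabilities Mtilde = sigmoid(E Wm + bm)."""
    e = np.asarray(e, dtype=np.float64)
    if e.shape[1] != state.arch.latent_dim:
        raise ValueError(
            f"embedding has {e.shape[1]} columns, expected {state.arch.latent_dim}"
        )
    return _sigmoid(e @ state.mask_W + state.mask_b)


def decode(state: ModelState, e: np.ndarray, m_pred: np.ndarray) -> np.ndarray:
    """Reconstruct expression from concat(embedding, predicted mask)."""
    e = np.asarray(e, dtype=np.float64)
    m_pred = np.asarray(m_pred, dtype=np.float64)
    if e.shape[1] != state.arch.latent_dim or m_pred.shape[1] != state.arch.input_dim:
        raise ValueError(
            f"decode expects ({state.arch.latent_dim}, {state.arch.input_dim}) "
            f"columns, got ({e.shape[1]}, {m_pred.shape[1]})"
        )
    return np.concatenate([e, m_pred], axis=1) @ state.dec_W + state.dec_b


def mask_loss(
    m: np.ndarray,
    m_pred: np.ndarray,
    eps: float = 1e-7,
    positive_term_only: bool = False,
) -> float:
    """Mean binary cross-entropy between the true and predicted mask.

    ``positive_term_only`` keeps only the -M log(Mtilde) term (the
    single-term form); the default includes the negative-class term so a
    constant Mtilde = 1 is not a degenerate optimum.
    """
    m = np.asarray(m, dtype=np.float64)
    m_pred = np.asarray(m_pred, dtype=np.float64)
    if m.shape != m_pred.shape:
        raise ValueError(f"shape mismatch: {m.shape} vs {m_pred.shape}")
    p = np.clip(m_pred, eps, 1.0 - eps)
    if positive_term_only:
        return float(-np.mean(m * np.log(p)))
    return float(-np.mean(m * np.log(p) + (1.0 - m) * np.log1p(-p)))


def _omega(m: np.ndarray, cfg: LossConfig) -> np.ndarray:
    lam = cfg.lambda_mask_weight
    if cfg.ablation == "unmasked_only":
        return 1.0 - m
    if cfg.ablation == "masked_only":
        return m
    return m * lam + (1.0 - m) * (1.0 - lam)


def reconstruction_loss(
    x: np.ndarray, x_hat: np.ndarray, m: np.ndarray, cfg: LossConfig
) -> float:
    """Mask-weighted mean squared reconstruction error."""
    x = np.asarray(x, dtype=np.float64)
    x_hat = np.asarray(x_hat, dtype=np.float64)
    m = np.asarray(m, dtype=np.float64)
    if not (x.shape == x_hat.shape == m.shape):
        raise ValueError(
            f"shape mismatch: x {x.shape}, x_hat {x_hat.shape}, m {m.shape}"
        )
    return float(np.mean(_omega(m, cfg) * (x - x_hat) ** 2))


def total_loss(lr: float, lm: float, cfg: LossConfig) -> float:
    """Combine the two losses; ``no_mask_loss`` drops the mask term entirely."""
    if cfg.ablation == "no_mask_loss":
        return float(lr)
    g = cfg.gamma_balance
    return float((1.0 - g) * lr + g * lm)


def loss_and_grads(
    state: ModelState,
    x: np.ndarray,
    xm: np.ndarray,
    m: np.ndarray,
    cfg: LossConfig,
):
    """One forward/backward pass.

    Returns ``(total, lr, lm, grads)`` where ``grads`` mirrors
    ``state.params()``. In ``no_mask_loss`` mode the mask-head gradients are
    zero (head frozen) while the reconstruction gradient still flows through
    it into the encoder.
    """
    x = np.asarray(x, dtype=np.float64)
    xm = np.asarray(xm, dtype=np.float64)
    m = np.asarray(m, dtype=np.float64)
    c, g = x.shape
    n = c * g
    lam_dim = state.arch.latent_dim

    e, inputs, preacts = _encode_cache(state, xm)
    m_pred = predict_mask(state, e)
    x_hat = decode(state, e, m_pred)

    lr = reconstruction_loss(x, x_hat, m, cfg)
    lm = mask_loss(m, m_pred, eps=cfg.eps, positive_term_only=cfg.positive_term_only)
    total = total_loss(lr, lm, cfg)

    grads: dict[str, np.ndarray] = {}

    # reconstruction branch
    coef_r = 1.0 if cfg.ablation == "no_mask_loss" else 1.0 - cfg.gamma_balance
    d_xhat = coef_r * 2.0 * _omega(m, cfg) * (x_hat - x) / n
    cat = np.concatenate([e, m_pred], axis=1)
    grads["dec_W"] = cat.T @ d_xhat
    grads["dec_b"] = d_xhat.sum(axis=0)
    d_cat = d_xhat @ state.dec_W.T
    d_e = d_cat[:, :lam_dim].copy()
    d_mpred = d_cat[:, lam_dim:].copy()

    # mask-estimation branch
    if cfg.ablation != "no_mask_loss" and cfg.gamma_balance > 0.0:
        p = np.clip(m_pred, cfg.eps, 1.0 - cfg.eps)
        inside = (m_pred > cfg.eps) & (m_pred < 1.0 - cfg.eps)
        if cfg.positive_term_only:
            d_bce = -(m / p) / n
        else:
            d_bce = (-(m / p) + (1.0 - m) / (1.0 - p)) / n
        d_mpred += cfg.gamma_balance * d_bce * inside

    d_zm = d_mpred * m_pred * (1.0 - m_pred)
    if cfg.ablation == "no_mask_loss":
        grads["mask_W"] = np.zeros_like(state.mask_W)
        grads["mask_b"] = np.zeros_like(state.mask_b)
    else:
        grads["mask_W"] = e.T @ d_zm
        grads["mask_b"] = d_zm.sum(axis=0)
    d_e += d_zm @ state.mask_W.T

    # encoder: final linear layer, then hidden layers in reverse
    grads[f"enc_W{len(state.enc_W) - 1}"] = inputs[-1].T @ d_e
    grads[f"enc_b{len(state.enc_W) - 1}"] = d_e.sum(axis=0)
    d_h = d_e @ state.enc_W[-1].T
    for l in range(len(preacts) - 1, -1, -1):
        d_z = d_h * _act_grad(preacts[l], state.arch.activation)
        grads[f"enc_W{l}"] = inputs[l].T @ d_z
        grads[f"enc_b{l}"] = d_z.sum(axis=0)
        d_h = d_z @ state.enc_W[l].T

    return total, lr, lm, grads


def save_checkpoint(
    state: ModelState, path: str | Path, loss_cfg: LossConfig | None = None
) -> None:
    """Serialize parameters plus architecture/loss hyperparameters to .npz."""
    meta = {
        "arch": {
            "input_dim": state.arch.input_dim,
            "hidden_dims": state.arch.hidden_dims,
            "latent_dim": state.arch.latent_dim,
            "activation": state.arch.activation,
        },
        "loss": None
        if loss_cfg is None
        else {
            "lambda_mask_weight": loss_cfg.lambda_mask_weight,
            "gamma_balance": loss_cfg.gamma_balance,
            "ablation": loss_cfg.ablation,
            "positive_term_only": loss_cfg.positive_term_only,
            "eps": loss_cfg.eps,
        },
    }
    arrays = {k: v for k, v in state.params().items()}
    np.savez(Path(path), _meta=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path: str | Path):
    """Inverse of :func:`save_checkpoint`; returns (state, loss_cfg_or_None)."""
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["_meta"]))
        arch = ArchitectureSpec(**meta["arch"])
        n_layers = len(arch.hidden_dims) + 1
        state = ModelState(
            arch=arch,
            enc_W=[data[f"enc_W{i}"] for i in range(n_layers)],
            enc_b=[data[f"enc_b{i}"] for i in range(n_layers)],
            mask_W=data["mask_W"],
            mask_b=data["mask_b"],
            dec_W=data["dec_W"],
            dec_b=data["dec_b"],
        )
    loss_cfg = None if meta["loss"] is None else LossConfig(**meta["loss"])
    return state, loss_cfg
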