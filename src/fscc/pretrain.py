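"""Stage-1 pre-training on base classes with a weighted CE + contrastive loss.

The training objective is L = L_CE + lambda * L_SCL.  L_CE is the mean
cross-entropy over the mini-batch.  L_SCL is the supervised contrastive loss:
for each sample i with at least one same-class companion in the batch,

    L_i = -(1 / (N_yi - 1)) * sum_{j != i, y_j = y_i}
            log( exp(z_i . z_j / tau) / sum_{k != i} exp(z_i . z_k / tau) )

summed over the batch.  Positives exclude the anchor itself (the N_yi - 1
normalizer presumes this); samples whose class appears only once in the batch
contribute zero.  By default embeddings are L2-normalized inside the loss —
the temperature tau = 0.07 is calibrated for unit-norm embeddings — while the
raw nonnegative features feed the classifier head and, later, the Tukey
transform.

Class-balanced mini-batches keep every class represented so contrastive
positives exist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._nn import Adam, Linear, softmax
from .backbone import Conv6Backbone
from .io_datasets import class_balanced_batches

__all__ = ["LossConfig", "PretrainConfig", "cross_entropy_loss",
           "supervised_contrastive_loss", "combined_loss", "pretrain",
           "PretrainResult"]

_PROB_EPS = 1e-12


@dataclass(frozen=True)
class LossConfig:
    """Weights of the combined pre-training objective."""

    lambda_scl: float = 0.05   # weight of the contrastive term
    tau: float = 0.07          # contrastive temperature
    normalize_embeddings: bool = True

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.lambda_scl < 0:
            raise ValueError("lambda_scl must be nonnegative")


@dataclass(frozen=True)
class PretrainConfig:
    """Optimization settings for the pre-training stage.

    The published recipe uses Adam at learning rate 0.05 with batch 128 for
    5 epochs on large datasets, or batch 32 for 50 epochs on small ones; 0.05
    is unusually high for Adam and smaller values are often better behaved.
    """

    batch_size: int = 128
    epochs: int = 5
    learning_rate: float = 0.05
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer.lower() != "adam":
            raise ValueError("only the adam optimizer is supported")


@dataclass
class PretrainResult:
    backbone: Conv6Backbone
    head: Linear
    log: pd.DataFrame  # columns: epoch, batch, ce, scl, total


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def cross_entropy_loss(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Mean over the batch of -log p(true class); p clamped at 1e-12."""
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels)
    if probabilities.ndim != 2:
        raise ValueError("probabilities must be (batch, classes)")
    if not np.allclose(probabilities.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    if labels.min() < 0 or labels.max() >= probabilities.shape[1]:
        raise ValueError("labels out of range")
    p_true = probabilities[np.arange(len(labels)), labels]
    return float(-np.log(np.clip(p_true, _PROB_EPS, None)).mean())


def _scl_value_and_grad(embeddings: np.ndarray, labels: np.ndarray,
                        tau: float) -> tuple[float, np.ndarray]:
    """Supervised contrastive loss and its gradient w.r.t. the embeddings."""
    z = np.asarray(embeddings, dtype=float)
    y = np.asarray(labels)
    m = len(z)
    if m < 2:
        raise ValueError("contrastive loss needs at least 2 samples")
    same = y[:, None] == y[None, :]
    np.fill_diagonal(same, False)
    n_pos = same.sum(axis=1)  # N_yi - 1
    active = n_pos > 0
    if not active.any():
        warnings.warn("all classes are singletons in this batch: contrastive loss is 0",
                      stacklevel=2)
        return 0.0, np.zeros_like(z)

    s = z @ z.T / tau
    off = ~np.eye(m, dtype=bool)
    # row-wise log-sum-exp over k != i, with max subtraction
    s_off = np.where(off, s, -np.inf)
    row_max = s_off.max(axis=1, keepdims=True)
    exp_s = np.exp(s_off - row_max)
    denom = exp_s.sum(axis=1, keepdims=True)
    log_z = (row_max + np.log(denom)).ravel()
    softmax_off = exp_s / denom

    with np.errstate(invalid="ignore", divide="ignore"):
        pos_mean = np.where(active, (np.where(same, s, 0.0)).sum(axis=1)
                            / np.maximum(n_pos, 1), 0.0)
    value = float(np.sum(np.where(active, -pos_mean + log_z, 0.0)))

    # dL/ds[i, k] = softmax_ik - 1[k positive of i]/n_pos_i, for active i
    g = softmax_off - np.where(same, 1.0, 0.0) / np.maximum(n_pos, 1)[:, None]
    g[~active] = 0.0
    g[~off] = 0.0
    grad = (g @ z + g.T @ z) / tau
    return value, grad


def supervised_contrastive_loss(embeddings: np.ndarray, labels: np.ndarray,
                                tau: float = 0.07) -> float:
    """Supervised contrastive loss over one batch (see module docstring)."""
    value, _ = _scl_value_and_grad(embeddings, labels, tau)
    return value


def combined_loss(ce: float, scl: float, lambda_scl: float) -> float:
    """Weighted total: ce + lambda_scl * scl."""
    if not (np.isfinite(ce) and np.isfinite(scl)):
        raise ValueError("loss components must be finite")
    return float(ce + lambda_scl * scl)


def _l2_normalize_with_grad(f: np.ndarray, eps: float = 1e-12):
    """Row-normalize; returns (z, backward) where backward maps dz -> df."""
    norms = np.maximum(np.linalg.norm(f, axis=1, keepdims=True), eps)
    z = f / norms

    def backward(dz: np.ndarray) -> np.ndarray:
        # d(f/|f|) = (dz - z (z . dz)) / |f|
        return (dz - z * (z * dz).sum(axis=1, keepdims=True)) / norms

    return z, backward


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def pretrain(backbone: Conv6Backbone, volumes: np.ndarray, labels: np.ndarray,
             config: PretrainConfig | None = None,
             loss_config: LossConfig | None = None,
             progress: bool = False) -> PretrainResult:
    """Train the extractor + linear head on the (normalized) base volumes.

    Volumes are expected already normalized per subtomogram (zero mean, unit
    variance); labels must cover at least 2 classes with >= 2 samples each.
    Deterministic under a fixed config seed.
    """
    config = config or PretrainConfig()
    loss_config = loss_config or LossConfig()
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("pre-training needs at least 2 base classes")
    if counts.min() < 2:
        raise ValueError("every base class needs at least 2 samples")
    class_index = {c: i for i, c in enumerate(classes)}
    dense = np.array([class_index[c] for c in labels])

    rng = np.random.default_rng(config.seed)
    head = Linear(backbone.config.feature_dim, len(classes), rng)
    opt = Adam(backbone.params() + head.params(), backbone.grads() + head.grads(),
               lr=config.learning_rate)
    batch_seeds = np.random.SeedSequence(config.seed).generate_state(config.epochs) % (2**31)

    rows = []
    for epoch in range(config.epochs):
        batches = class_balanced_batches(dense, min(config.batch_size, len(labels)),
                                         seed=int(batch_seeds[epoch]))
        for b, idx in enumerate(batches):
            xb, yb = volumes[idx], dense[idx]
            opt.zero_grad()
            feats = backbone.forward(xb, train=True)
            logits = head.forward(feats)
            probs = softmax(logits)
            ce = cross_entropy_loss(probs, yb)
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            dfeat = head.backward(dlogits)

            if loss_config.lambda_scl > 0:
                if loss_config.normalize_embeddings:
                    z, unnorm = _l2_normalize_with_grad(feats)
                    scl, dz = _scl_value_and_grad(z, yb, loss_config.tau)
                    dfeat = dfeat + loss_config.lambda_scl * unnorm(dz)
                else:
                    scl, dz = _scl_value_and_grad(feats, yb, loss_config.tau)
                    dfeat = dfeat + loss_config.lambda_scl * dz
            else:
                scl = supervised_contrastive_loss(
                    feats if not loss_config.normalize_embeddings
                    else feats / np.maximum(np.linalg.norm(feats, axis=1, keepdims=True), 1e-12),
                    yb, loss_config.tau)

            backbone.backward(dfeat)
            opt.step()
            total = combined_loss(ce, scl, loss_config.lambda_scl)
            rows.append({"epoch": epoch, "batch": b, "ce": ce, "scl": scl, "total": total})
        if progress:
            last = rows[-1]
            print(f"epoch {epoch}: ce={last['ce']:.4f} scl={last['scl']:.4f} "
                  f"total={last['total']:.4f}")
    return PretrainResult(backbone=backbone, head=head, log=pd.DataFrame(rows))
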