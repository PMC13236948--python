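"""Linear probes on frozen features, head ensembles, and moment matching.

The frozen-representation protocol trains a single linear classification head
on source-domain features by cross-entropy with weight decay, keeps the
checkpoint with the best validation accuracy (early stopping, patience 5),
and evaluates it unchanged on the shifted target domain.  Head ensembles
re-run the same training from different initialization seeds.  Moment
matching is the channel-wise affine alignment of source features to target
statistics estimated from the field calibration subset.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ProbeHyper",
    "LinearHead",
    "ChannelStats",
    "softmax",
    "cross_entropy",
    "train_linear_head",
    "train_head_ensemble",
    "channel_stats",
    "moment_match",
]

EPS = 1e-12


@dataclass(frozen=True)
class ProbeHyper:
    """Full-batch gradient-descent schedule for the linear head.

    lr / epochs are probe-scale choices; weight decay 0.01 and patience 5
    follow the study's training recipe.
    """

    lr: float = 0.5
    epochs: int = 300
    weight_decay: float = 0.01
    patience: int = 5
    init_std: float = 0.5


@dataclass
class LinearHead:
    weights: np.ndarray  # feature_dim x K
    bias: np.ndarray  # K
    seed: int
    training_log: list[tuple[int, float]] = field(default_factory=list)

    def logits(self, features: np.ndarray) -> np.ndarray:
        return features @ self.weights + self.bias

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.logits(features).argmax(axis=1)


@dataclass
class ChannelStats:
    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        if len(self.mean) != len(self.std):
            raise ValueError("mean and std lengths differ")
        if np.any(self.std < 0):
            raise ValueError("std must be non-negative")


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, overflow-guarded by max subtraction."""
    z = np.atleast_2d(np.asarray(logits, dtype=np.float64))
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    return p if np.asarray(logits).ndim > 1 else p[0]


def cross_entropy(probabilities: np.ndarray, labels) -> float:
    """Mean negative log-probability of the true class.

    Zero true-class probabilities are clamped at ``EPS`` with a warning, so
    degenerate one-hot mistakes yield a large finite loss.
    """
    p = np.atleast_2d(np.asarray(probabilities, dtype=np.float64))
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 0 or labels.max() >= p.shape[1]:
        raise ValueError("labels out of range")
    true_p = p[np.arange(len(labels)), labels]
    if np.any(true_p <= 0):
        warnings.warn("true-class probability of 0 clamped", RuntimeWarning)
        true_p = np.clip(true_p, EPS, None)
    return float(-np.mean(np.log(true_p)))


def _accuracy(head_w, head_b, X, y) -> float:
    return float(np.mean((X @ head_w + head_b).argmax(axis=1) == y))


def train_linear_head(
    train_features: np.ndarray,
    train_labels,
    val_features: np.ndarray,
    val_labels,
    hyper: ProbeHyper = ProbeHyper(),
    seed: int = 0,
) -> LinearHead:
    """Fit a linear head by full-batch gradient descent on the regularized
    cross-entropy, keeping the checkpoint with the highest validation
    accuracy (early stopping with the configured patience).

    Deterministic given (features, labels, hyper, seed).
    """
    X = np.asarray(train_features, dtype=np.float64)
    y = np.asarray(train_labels, dtype=int)
    Xv = np.asarray(val_features, dtype=np.float64)
    yv = np.asarray(val_labels, dtype=int)
    K = int(y.max()) + 1
    if K < 2:
        raise ValueError("need at least two classes")
    if X.shape[1] != Xv.shape[1]:
        raise ValueError("train/val feature dims differ")
    n, d = X.shape
    rng = np.random.default_rng(seed)
    W = hyper.init_std * rng.standard_normal((d, K))
    b = np.zeros(K)
    onehot = np.zeros((n, K))
    onehot[np.arange(n), y] = 1.0

    best = (-1.0, W.copy(), b.copy())
    stale = 0
    log: list[tuple[int, float]] = []
    for epoch in range(hyper.epochs):
        P = softmax(X @ W + b)
        loss = cross_entropy(P, y) + hyper.weight_decay * float(np.sum(W * W))
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}: {loss}")
        G = (P - onehot) / n
        W -= hyper.lr * (X.T @ G + 2.0 * hyper.weight_decay * W)
        b -= hyper.lr * G.sum(axis=0)
        val_acc = _accuracy(W, b, Xv, yv)
        log.append((epoch, val_acc))
        if val_acc > best[0]:
            best = (val_acc, W.copy(), b.copy())
            stale = 0
        else:
            stale += 1
            if stale > hyper.patience:
                break
    return LinearHead(weights=best[1], bias=best[2], seed=seed, training_log=log)


def train_head_ensemble(
    train_features,
    train_labels,
    val_features,
    val_labels,
    hyper: ProbeHyper = ProbeHyper(),
    seeds=(0, 1, 2, 3, 4),
) -> list[LinearHead]:
    """M independently initialized heads on the same frozen features."""
    seeds = list(seeds)
    if len(seeds) < 2:
        raise ValueError("an ensemble needs at least two members")
    if len(set(seeds)) != len(seeds):
        warnings.warn("duplicate seeds: ensemble members will coincide", RuntimeWarning)
    return [
        train_linear_head(train_features, train_labels, val_features, val_labels,
                          hyper=hyper, seed=s)
        for s in seeds
    ]


def channel_stats(features: np.ndarray) -> ChannelStats:
    """Per-channel mean and standard deviation (n-1 normalization)."""
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least two rows")
    return ChannelStats(mean=X.mean(axis=0), std=X.std(axis=0, ddof=1))


def moment_match(
    source_features: np.ndarray,
    source_stats: ChannelStats,
    target_stats: ChannelStats,
) -> np.ndarray:
    """Channel-wise affine alignment h~ = sigma_t * (h - mu_s) / sigma_s + mu_t.

    Channels with near-zero source spread fall back to sigma_s = EPS (logged),
    so the transform stays finite.
    """
    X = np.asarray(source_features, dtype=np.float64)
    if X.shape[1] != len(source_stats.mean) or X.shape[1] != len(target_stats.mean):
        raise ValueError("feature dimension mismatch")
    if np.array_equal(source_stats.mean, target_stats.mean) and np.array_equal(
        source_stats.std, target_stats.std
    ):
        return X.copy()  # exact identity, no float round trip
    sigma_s = source_stats.std.copy()
    degenerate = sigma_s < EPS
    if degenerate.any():
        logger.warning("%d channels with ~zero source std clamped", degenerate.sum())
        sigma_s[degenerate] = EPS
    return target_stats.std * (X - source_stats.mean) / sigma_s + target_stats.mean
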