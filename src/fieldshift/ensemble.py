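"""Ensemble aggregation and the epistemic-aleatoric decomposition.

The predictive distribution of an M-member ensemble is the arithmetic mean
of member softmax outputs.  Total predictive entropy H[p_bar] splits into an
aleatoric proxy (mean member entropy) and an epistemic proxy (the mutual
information between the prediction and the member index):

    H[p_bar] = E_m[H[p^(m)]] + MI,   MI >= 0 by Jensen.

Scores for the ensemble path are computed from the mean probabilities (via
log-mean-probability pseudo-logits, the unique choice whose T = 1 softmax
reproduces the ensemble predictive distribution); the decomposition always
uses the raw member outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EnsembleBatch",
    "UncertaintyDecomposition",
    "ensemble_mean",
    "decompose_uncertainty",
    "ensemble_predictive_logits",
]

_CLAMP = 1e-12


@dataclass
class EnsembleBatch:
    """M x N x K member probabilities (each member-sample row on the simplex)."""

    member_probabilities: np.ndarray
    member_seeds: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        p = np.asarray(self.member_probabilities, dtype=np.float64)
        if p.ndim != 3:
            raise ValueError("member_probabilities must be M x N x K")
        if p.shape[0] < 2:
            raise ValueError("an ensemble needs M >= 2 members")
        if np.any(p < -1e-12) or np.any(np.abs(p.sum(axis=2) - 1.0) > 1e-8):
            raise ValueError("member rows must be probability vectors")
        self.member_probabilities = p


@dataclass
class UncertaintyDecomposition:
    predictive_entropy: np.ndarray  # nats
    aleatoric: np.ndarray  # nats
    epistemic_mi: np.ndarray  # nats


def _entropy(p: np.ndarray) -> np.ndarray:
    """Shannon entropy along the last axis, 0 log 0 = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(p > 0, np.log(p), 0.0)
    return -np.sum(p * logp, axis=-1)


def ensemble_mean(batch: EnsembleBatch) -> np.ndarray:
    """Arithmetic member mean; rows remain simplex-valued."""
    return batch.member_probabilities.mean(axis=0)


def decompose_uncertainty(batch: EnsembleBatch) -> UncertaintyDecomposition:
    """Per-sample total / aleatoric / epistemic uncertainty in nats.

    Epistemic MI is computed as the difference, so the additive identity
    holds exactly; it is non-negative up to floating error.
    """
    p = batch.member_probabilities
    total = _entropy(ensemble_mean(batch))
    aleatoric = _entropy(p).mean(axis=0)
    return UncertaintyDecomposition(
        predictive_entropy=total,
        aleatoric=aleatoric,
        epistemic_mi=total - aleatoric,
    )


def ensemble_predictive_logits(mean_probabilities: np.ndarray) -> np.ndarray:
    """Elementwise log of the mean probabilities; softmax at T = 1 recovers
    the input.  Zero entries are clamped at 1e-12 with a warning."""
    p = np.asarray(mean_probabilities, dtype=np.float64)
    if np.any(p <= 0):
        warnings.warn("zero mean probabilities clamped at 1e-12", RuntimeWarning)
        p = np.clip(p, _CLAMP, None)
    return np.log(p)
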