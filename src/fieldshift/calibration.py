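"""Post-hoc temperature scaling and calibration quality metrics.

Temperature scaling divides every logit vector by a single scalar T fitted by
negative-log-likelihood minimization on a calibration split; it softens (or
sharpens) the predictive distribution while preserving the argmax, so
accuracy is untouched.  Calibration quality is summarized by the reliability
table over M = 15 equal-width confidence bins, its scalar ECE, and the
strictly proper multiclass Brier score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .probe import cross_entropy, softmax

__all__ = [
    "TemperatureFit",
    "ReliabilityTable",
    "apply_temperature",
    "fit_temperature",
    "expected_calibration_error",
    "brier_score",
    "reliability_table",
]

T_BOUNDS = (0.01, 1000.0)
T_XATOL = 1e-6
DEFAULT_BINS = 15


@dataclass
class TemperatureFit:
    temperature: float
    nll_at_fit: float
    nll_at_one: float
    calibration_set_id: str = ""
    at_bound: bool = False
    optimizer_trace: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class ReliabilityTable:
    """Per-bin confidence/accuracy bookkeeping over equal-width bins.

    Last bin is right-closed, the others right-open; recomputing ECE from the
    table reproduces the scalar bit-exactly.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    mean_confidence: np.ndarray
    accuracy: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def ece(self) -> float:
        occ = self.counts > 0
        gaps = np.abs(self.accuracy[occ] - self.mean_confidence[occ])
        return float(np.sum(self.counts[occ] * gaps) / self.n)


def apply_temperature(logits: np.ndarray, T: float) -> np.ndarray:
    """Row-wise softmax of z / T.  T = 1 recovers the plain softmax; any
    positive T preserves the per-row argmax."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return softmax(np.asarray(logits, dtype=np.float64) / T)


def fit_temperature(
    logits: np.ndarray,
    labels,
    calibration_set_id: str = "",
) -> TemperatureFit:
    """Fit T by bounded 1-D NLL minimization on the calibration split.

    A Brent-style bounded scalar search over [0.01, 1000] replaces the
    usual quasi-Newton fit: the problem has a single bounded parameter and
    an identical optimum.  If the NLL decreases monotonically to a bound
    (e.g. every prediction already correct with huge margins), the bound is
    returned with ``at_bound`` set.
    """
    logits = np.atleast_2d(np.asarray(logits, dtype=np.float64))
    labels = np.asarray(labels, dtype=int)
    if len(logits) < 2:
        raise ValueError("need at least two calibration samples")
    trace: list[tuple[float, float]] = []

    def nll(T: float) -> float:
        v = cross_entropy(apply_temperature(logits, T), labels)
        trace.append((float(T), v))
        return v

    res = minimize_scalar(
        nll, bounds=T_BOUNDS, method="bounded", options={"xatol": T_XATOL}
    )
    T = float(res.x)
    nll_fit = float(res.fun)
    at_bound = T <= T_BOUNDS[0] + 10 * T_XATOL or T >= T_BOUNDS[1] * (1 - 1e-6)
    # plateau / monotone descent into a bound: report the bound itself
    for bound in T_BOUNDS:
        v = cross_entropy(apply_temperature(logits, bound), labels)
        if v <= nll_fit + 1e-12:
            T, nll_fit, at_bound = bound, v, True
            break
    nll_one = cross_entropy(apply_temperature(logits, 1.0), labels)
    if nll_one < nll_fit:  # optimizer never beats T=1? take T=1 then
        T, nll_fit, at_bound = 1.0, nll_one, False
    return TemperatureFit(
        temperature=T,
        nll_at_fit=nll_fit,
        nll_at_one=nll_one,
        calibration_set_id=calibration_set_id,
        at_bound=at_bound,
        optimizer_trace=trace,
    )


def reliability_table(
    probabilities: np.ndarray, labels, n_bins: int = DEFAULT_BINS
) -> ReliabilityTable:
    """Bin max-probability confidences into ``n_bins`` equal-width bins."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    p = np.atleast_2d(np.asarray(probabilities, dtype=np.float64))
    labels = np.asarray(labels, dtype=int)
    conf = p.max(axis=1)
    pred = p.argmax(axis=1)
    correct = pred == labels
    idx = np.minimum((conf * n_bins).astype(int), n_bins - 1)
    counts = np.zeros(n_bins, dtype=int)
    mean_conf = np.zeros(n_bins)
    acc = np.zeros(n_bins)
    for m in range(n_bins):
        sel = idx == m
        counts[m] = sel.sum()
        if counts[m]:
            mean_conf[m] = conf[sel].mean()
            acc[m] = correct[sel].mean()
    return ReliabilityTable(
        bin_edges=np.linspace(0.0, 1.0, n_bins + 1),
        counts=counts,
        mean_confidence=mean_conf,
        accuracy=acc,
    )


def expected_calibration_error(
    probabilities: np.ndarray, labels, n_bins: int = DEFAULT_BINS
) -> float:
    """Bin-weighted mean absolute confidence/accuracy gap; empty bins
    contribute nothing."""
    return reliability_table(probabilities, labels, n_bins).ece()


def brier_score(probabilities: np.ndarray, labels) -> float:
    """Mean multiclass squared error between probability vectors and one-hot
    labels (summed over classes, averaged over samples); range [0, 2]."""
    p = np.atleast_2d(np.asarray(probabilities, dtype=np.float64))
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 0 or labels.max() >= p.shape[1]:
        raise ValueError("labels out of range")
    onehot = np.zeros_like(p)
    onehot[np.arange(len(labels)), labels] = 1.0
    return float(np.mean(np.sum((onehot - p) ** 2, axis=1)))
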