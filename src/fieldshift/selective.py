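"""Confidence scoring, abstention policies, coverage-risk analysis, and
threshold-free open-set metrics.

Four post-hoc confidence scores are derived from the temperature-scaled
classifier: maximum softmax probability, normalized-entropy confidence,
top-two margin, and the energy score log-sum-exp(z/T).  Larger always means
more confident.  A prediction is emitted iff score >= tau; coverage is the
answered fraction, selective risk the error rate among answered samples.
Thresholds are derived only from calibration data and transferred unchanged.
Unknown-class detection treats unknowns as the positives, detected by low
confidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .probe import softmax

__all__ = [
    "ScoreVector",
    "ThresholdPolicy",
    "CoverageRiskCurve",
    "SCORE_METHODS",
    "confidence_score",
    "selective_metrics",
    "coverage_risk_curve",
    "threshold_for_coverage",
    "threshold_for_risk",
    "rejection_rates",
    "auroc_unknown",
    "aupr_unknown",
    "fpr_at_95tpr",
]

SCORE_METHODS = ("msp", "entropy", "margin", "energy")


@dataclass
class ScoreVector:
    scores: np.ndarray
    method: str
    temperature_used: float


@dataclass
class ThresholdPolicy:
    """A calibration-derived threshold, applied unchanged to test data.

    ``tau = +inf`` with ``abstain_all`` set is the sentinel for an infeasible
    fixed-risk target: no threshold met the risk bound, so nothing is
    answered.
    """

    strategy: str
    target_level: float
    tau: float
    calibration_set_id: str = ""
    achieved_calibration_coverage: float = 0.0
    achieved_calibration_risk: float | None = None
    abstain_all: bool = False


@dataclass
class CoverageRiskCurve:
    points: list[tuple[float, float, float | None]]  # (tau, coverage, risk)


def _as_scores(scores) -> np.ndarray:
    if isinstance(scores, ScoreVector):
        return np.asarray(scores.scores, dtype=np.float64)
    return np.asarray(scores, dtype=np.float64)


def confidence_score(logits: np.ndarray, T: float = 1.0, method: str = "msp") -> ScoreVector:
    """Per-sample confidence from temperature-scaled logits."""
    if method not in SCORE_METHODS:
        raise ValueError(f"unknown score method {method!r}")
    if T <= 0:
        raise ValueError("temperature must be positive")
    z = np.atleast_2d(np.asarray(logits, dtype=np.float64)) / T
    K = z.shape[1]
    if K < 2:
        raise ValueError("need K >= 2")
    if method == "energy":
        m = z.max(axis=1, keepdims=True)
        s = (m[:, 0] + np.log(np.sum(np.exp(z - m), axis=1)))
    else:
        p = softmax(z)
        if method == "msp":
            s = p.max(axis=1)
        elif method == "margin":
            part = np.partition(p, K - 2, axis=1)
            s = part[:, -1] - part[:, -2]
        else:  # entropy confidence, normalized to [0, 1]
            with np.errstate(divide="ignore", invalid="ignore"):
                logp = np.where(p > 0, np.log(p), 0.0)
            H = -np.sum(p * logp, axis=1)
            s = 1.0 - H / math.log(K)
    return ScoreVector(scores=np.asarray(s, dtype=np.float64), method=method,
                       temperature_used=float(T))


def selective_metrics(scores, correct, tau: float):
    """(coverage, selective risk) at threshold tau; risk is None at coverage 0."""
    s = _as_scores(scores)
    correct = np.asarray(correct, dtype=bool)
    if len(s) != len(correct):
        raise ValueError("scores and correctness have different lengths")
    answered = s >= tau
    coverage = float(answered.mean())
    if coverage == 0.0:
        return coverage, None
    risk = float(np.mean(~correct[answered]))
    return coverage, risk


def coverage_risk_curve(scores, correct) -> CoverageRiskCurve:
    """One operating point per distinct score value plus the coverage-0
    boundary; coverage is non-increasing in tau."""
    s = _as_scores(scores)
    correct = np.asarray(correct, dtype=bool)
    if len(s) == 0:
        raise ValueError("need at least one sample")
    taus = np.unique(s).tolist() + [np.inf]
    points = []
    for tau in taus:
        cov, risk = selective_metrics(s, correct, tau)
        points.append((float(tau), cov, risk))
    return CoverageRiskCurve(points=points)


def threshold_for_coverage(calib_scores, target_coverage: float,
                           calibration_set_id: str = "") -> ThresholdPolicy:
    """tau = largest calibration score value whose coverage is >= target.

    Under ties the achieved coverage may exceed the nominal target.
    """
    s = _as_scores(calib_scores)
    if len(s) == 0:
        raise ValueError("empty calibration set")
    if not 0.0 < target_coverage <= 1.0:
        raise ValueError("target coverage must lie in (0, 1]")
    best_tau, best_cov = None, None
    for tau in np.unique(s)[::-1]:  # descending: largest feasible tau first
        cov = float(np.mean(s >= tau))
        if cov >= target_coverage:
            best_tau, best_cov = float(tau), cov
            break
    if best_tau is None:  # only possible via float pathologies; answer all
        best_tau, best_cov = float(s.min()), 1.0
    return ThresholdPolicy(
        strategy="fixed_coverage", target_level=target_coverage, tau=best_tau,
        calibration_set_id=calibration_set_id,
        achieved_calibration_coverage=best_cov,
    )


def threshold_for_risk(calib_scores, calib_correct, target_risk: float,
                       calibration_set_id: str = "") -> ThresholdPolicy:
    """Among candidate taus (the distinct calibration scores), pick the one
    maximizing calibration coverage subject to calibration selective risk
    <= target; the abstain-all sentinel if no tau is feasible."""
    s = _as_scores(calib_scores)
    correct = np.asarray(calib_correct, dtype=bool)
    if not 0.0 <= target_risk < 1.0:
        raise ValueError("target risk must lie in [0, 1)")
    best = None  # (coverage, tau, risk)
    for tau in np.unique(s):
        cov, risk = selective_metrics(s, correct, float(tau))
        if risk is not None and risk <= target_risk:
            if best is None or cov > best[0] or (cov == best[0] and tau > best[1]):
                best = (cov, float(tau), risk)
    if best is None:
        return ThresholdPolicy(
            strategy="fixed_risk", target_level=target_risk, tau=math.inf,
            calibration_set_id=calibration_set_id,
            achieved_calibration_coverage=0.0, achieved_calibration_risk=None,
            abstain_all=True,
        )
    return ThresholdPolicy(
        strategy="fixed_risk", target_level=target_risk, tau=best[1],
        calibration_set_id=calibration_set_id,
        achieved_calibration_coverage=best[0], achieved_calibration_risk=best[2],
    )


def rejection_rates(known_scores, unknown_scores, tau: float):
    """(unknown rejection, known rejection): fraction of each set scoring
    below tau."""
    ks, us = _as_scores(known_scores), _as_scores(unknown_scores)
    if len(ks) == 0 or len(us) == 0:
        raise ValueError("both score sets must be non-empty")
    return float(np.mean(us < tau)), float(np.mean(ks < tau))


def auroc_unknown(known_scores, unknown_scores) -> float:
    """Probability a random unknown scores lower than a random known,
    ties counted one half (Mann-Whitney orientation: unknowns are the
    low-score detection positives)."""
    ks, us = _as_scores(known_scores), _as_scores(unknown_scores)
    if len(ks) == 0 or len(us) == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([ks, us]))
    r_known = ranks[: len(ks)].sum()
    u = r_known - len(ks) * (len(ks) + 1) / 2.0  # pairs where known > unknown (+ ties/2)
    return float(u / (len(ks) * len(us)))


def _detection_curve(known_scores, unknown_scores):
    """Threshold sweep for the low-score-detects-unknown rule.

    Returns per-candidate-tau arrays (tpr, fpr, n_detected_unknown,
    n_flagged_known, n_flagged_total), where flagged means score < tau; taus
    run over distinct observed scores plus +inf (flag everything).
    """
    ks, us = _as_scores(known_scores), _as_scores(unknown_scores)
    taus = np.concatenate([np.unique(np.concatenate([ks, us])), [np.inf]])
    tp = np.array([(us < t).sum() for t in taus], dtype=float)
    fp = np.array([(ks < t).sum() for t in taus], dtype=float)
    return taus, tp, fp, len(us), len(ks)


def aupr_unknown(known_scores, unknown_scores) -> float:
    """Average precision of the low-score-detects-unknown ranking, with step
    interpolation (sum of precision x recall increments)."""
    if len(_as_scores(known_scores)) == 0 or len(_as_scores(unknown_scores)) == 0:
        raise ValueError("both score sets must be non-empty")
    _, tp, fp, n_u, _ = _detection_curve(known_scores, unknown_scores)
    ap = 0.0
    prev_recall = 0.0
    for tpi, fpi in zip(tp, fp):
        if tpi + fpi == 0:
            continue
        recall = tpi / n_u
        precision = tpi / (tpi + fpi)
        ap += precision * (recall - prev_recall)
        prev_recall = recall
    return float(ap)


def fpr_at_95tpr(known_scores, unknown_scores) -> float:
    """Fraction of knowns flagged as unknown at the least conservative
    threshold whose unknown true-positive rate is >= 0.95 (step function,
    no interpolation)."""
    if len(_as_scores(known_scores)) == 0 or len(_as_scores(unknown_scores)) == 0:
        raise ValueError("both score sets must be non-empty")
    _, tp, fp, n_u, n_k = _detection_curve(known_scores, unknown_scores)
    feasible = tp / n_u >= 0.95
    return float((fp[feasible] / n_k).min())
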