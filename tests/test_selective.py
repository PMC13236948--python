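"""Confidence scores, abstention policies, and open-set metrics against
enumeration oracles."""

import itertools
import math

import numpy as np
import pytest

from fieldshift.selective import (
    auroc_unknown,
    aupr_unknown,
    confidence_score,
    coverage_risk_curve,
    fpr_at_95tpr,
    rejection_rates,
    selective_metrics,
    threshold_for_coverage,
    threshold_for_risk,
)


def logits_of(probs):
    return np.log(np.asarray(probs, dtype=float))


class TestConfidenceScore:
    def test_uniform_closed_forms(self):
        K = 6
        z = np.zeros((3, K))
        assert np.allclose(confidence_score(z, 1.0, "msp").scores, 1 / K)
        assert np.allclose(confidence_score(z, 1.0, "entropy").scores, 0.0, atol=1e-12)
        assert np.allclose(confidence_score(z, 1.0, "margin").scores, 0.0, atol=1e-12)
        assert np.allclose(confidence_score(z, 1.0, "energy").scores, math.log(K))

    def test_one_hot_extremes(self):
        z = logits_of([[1 - 2e-12, 1e-12, 1e-12]])
        for method, expect in (("msp", 1.0), ("entropy", 1.0), ("margin", 1.0)):
            s = confidence_score(z, 1.0, method).scores[0]
            assert s == pytest.approx(expect, abs=1e-9)

    def test_direct_evaluation(self):
        z = logits_of([[0.7, 0.2, 0.1]])
        assert confidence_score(z, 1.0, "msp").scores[0] == pytest.approx(0.7)
        assert confidence_score(z, 1.0, "margin").scores[0] == pytest.approx(0.5)
        H = -(0.7 * math.log(0.7) + 0.2 * math.log(0.2) + 0.1 * math.log(0.1))
        assert confidence_score(z, 1.0, "entropy").scores[0] == pytest.approx(
            1 - H / math.log(3)
        )

    def test_energy_shift_equivariance(self, rng):
        z = rng.standard_normal((40, 5))
        for T in (0.5, 1.0, 3.0):
            a = confidence_score(z, T, "energy").scores
            b = confidence_score(z + 2.5, T, "energy").scores
            assert np.allclose(b - a, 2.5 / T, atol=1e-10)

    def test_msp_margin_invariant_to_nontop_relabeling(self, rng):
        z = rng.standard_normal((30, 6))
        top = z.argmax(1)
        zp = z.copy()
        # permute the non-top columns per row
        for i in range(len(z)):
            others = [j for j in range(6) if j != top[i]]
            zp[i, np.roll(others, 2)] = z[i, others]
        for method in ("msp", "margin", "entropy", "energy"):
            assert np.allclose(
                confidence_score(z, 1.3, method).scores,
                confidence_score(zp, 1.3, method).scores,
                atol=1e-10,
            )

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            confidence_score(np.zeros((1, 2)), 1.0, "mahalanobis")


class TestSelectiveMetrics:
    def test_tau_extremes(self):
        s = np.array([0.2, 0.5, 0.9])
        correct = np.array([True, False, True])
        assert selective_metrics(s, correct, -np.inf) == (1.0, pytest.approx(1 / 3))
        cov, risk = selective_metrics(s, correct, 1.1)
        assert cov == 0.0 and risk is None

    def test_four_sample_enumeration(self):
        s = np.array([0.9, 0.8, 0.4, 0.2])
        correct = np.array([True, False, True, False])
        cov, risk = selective_metrics(s, correct, 0.5)
        assert cov == 0.5 and risk == 0.5

    def test_curve_consistency_and_monotonicity(self, rng):
        s = rng.random(60)
        correct = rng.random(60) > 0.4
        curve = coverage_risk_curve(s, correct)
        covs = [c for _, c, _ in curve.points]
        assert covs == sorted(covs, reverse=True)
        assert covs[0] == 1.0 and covs[-1] == 0.0
        for tau, cov, risk in curve.points:
            assert (cov, risk) == selective_metrics(s, correct, tau)

    def test_perfect_ranking_gives_zero_risk(self):
        s = np.array([0.9, 0.8, 0.7, 0.2, 0.1])
        correct = np.array([True, True, True, False, False])
        for tau, cov, risk in coverage_risk_curve(s, correct).points:
            if risk is not None and cov <= 0.6:
                assert risk == 0.0

    def test_constant_scores_two_coverages(self):
        curve = coverage_risk_curve(np.full(5, 0.5), np.ones(5, dtype=bool))
        assert sorted({c for _, c, _ in curve.points}) == [0.0, 1.0]


class TestThresholdPolicies:
    def test_fixed_coverage_by_inspection(self):
        s = np.arange(0.1, 1.05, 0.1)
        pol = threshold_for_coverage(s, 0.8)
        assert pol.tau == pytest.approx(0.3)
        assert pol.achieved_calibration_coverage == pytest.approx(0.8)

    def test_target_one_answers_everything(self):
        s = np.array([0.3, 0.6, 0.9])
        pol = threshold_for_coverage(s, 1.0)
        assert pol.tau == pytest.approx(0.3)
        assert pol.achieved_calibration_coverage == 1.0

    def test_ties_overshoot_matches_scan_oracle(self):
        s = np.array([0.5] * 6 + [0.9] * 4)
        pol = threshold_for_coverage(s, 0.5)
        # scan oracle: largest tau among observed values with coverage >= 0.5
        best = max(
            t for t in np.unique(s) if np.mean(s >= t) >= 0.5
        )
        assert pol.tau == pytest.approx(best)
        assert pol.achieved_calibration_coverage > 0.5

    def test_fixed_risk_all_correct(self):
        s = np.array([0.2, 0.5, 0.8])
        pol = threshold_for_risk(s, np.ones(3, dtype=bool), 0.05)
        assert pol.tau == pytest.approx(0.2)
        assert pol.achieved_calibration_coverage == 1.0
        assert pol.achieved_calibration_risk == 0.0

    def test_fixed_risk_all_wrong_abstains(self):
        pol = threshold_for_risk(np.array([0.2, 0.5]), np.zeros(2, dtype=bool), 0.1)
        assert pol.abstain_all
        assert pol.tau == math.inf
        cov, risk = selective_metrics(np.array([0.3, 0.9]), np.array([1, 1], bool), pol.tau)
        assert cov == 0.0 and risk is None

    @pytest.mark.parametrize("seed", range(6))
    def test_fixed_risk_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.random(20)
        correct = rng.random(20) > 0.5
        target = 0.25
        pol = threshold_for_risk(s, correct, target)
        feasible = []
        for tau in np.unique(s):
            cov, risk = selective_metrics(s, correct, tau)
            if risk is not None and risk <= target:
                feasible.append((cov, tau))
        if not feasible:
            assert pol.abstain_all
        else:
            best_cov = max(c for c, _ in feasible)
            assert pol.achieved_calibration_coverage == pytest.approx(best_cov)


class TestRejectionRates:
    def test_extremes_and_separation(self):
        known, unknown = np.array([0.8, 0.9]), np.array([0.1, 0.2])
        assert rejection_rates(known, unknown, 0.0) == (0.0, 0.0)
        assert rejection_rates(known, unknown, 0.5) == (1.0, 0.0)

    def test_interleaved_counting(self):
        known = np.array([0.1, 0.5, 0.9])
        unknown = np.array([0.2, 0.6, 0.8])
        u, k = rejection_rates(known, unknown, 0.55)
        assert u == pytest.approx(1 / 3)
        assert k == pytest.approx(2 / 3)


def auroc_oracle(known, unknown):
    total = 0.0
    for u in unknown:
        for k in known:
            total += 1.0 if u < k else (0.5 if u == k else 0.0)
    return total / (len(known) * len(unknown))


def aupr_oracle(known, unknown):
    """Precision/recall staircase over candidate thresholds."""
    taus = sorted(set(np.concatenate([known, unknown]))) + [np.inf]
    ap, prev_r = 0.0, 0.0
    for t in taus:
        tp = np.sum(unknown < t)
        fp = np.sum(known < t)
        if tp + fp == 0:
            continue
        r, p = tp / len(unknown), tp / (tp + fp)
        ap += p * (r - prev_r)
        prev_r = r
    return ap


class TestOpenSetMetrics:
    def test_perfect_separation(self):
        known, unknown = np.array([0.9, 0.8]), np.array([0.1, 0.2])
        assert auroc_unknown(known, unknown) == 1.0
        assert aupr_unknown(known, unknown) == 1.0
        assert fpr_at_95tpr(known, unknown) == 0.0

    def test_identical_multisets(self):
        s = np.array([0.3, 0.5, 0.7])
        assert auroc_unknown(s, s) == 0.5
        assert fpr_at_95tpr(np.full(3, 0.5), np.full(4, 0.5)) == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_auroc_matches_pairwise_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        known = np.round(rng.random(20), 1)
        unknown = np.round(rng.random(20), 1)
        assert auroc_unknown(known, unknown) == pytest.approx(
            auroc_oracle(known, unknown), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(8))
    def test_aupr_matches_staircase_oracle(self, seed):
        rng = np.random.default_rng(seed)
        known, unknown = rng.random(15), rng.random(10)
        assert aupr_unknown(known, unknown) == pytest.approx(
            aupr_oracle(known, unknown), abs=1e-12
        )

    def test_aupr_approaches_prevalence_when_uninformative(self):
        rng = np.random.default_rng(3)
        known, unknown = rng.random(4000), rng.random(1000)
        assert aupr_unknown(known, unknown) == pytest.approx(0.2, abs=0.03)

    @pytest.mark.parametrize("seed", range(6))
    def test_fpr95_matches_threshold_scan(self, seed):
        rng = np.random.default_rng(seed)
        known = rng.normal(0.6, 0.2, 20)
        unknown = rng.normal(0.4, 0.2, 20)
        got = fpr_at_95tpr(known, unknown)
        best = 1.0
        for t in np.concatenate([np.unique(np.concatenate([known, unknown])), [np.inf]]):
            if np.mean(unknown < t) >= 0.95:
                best = min(best, np.mean(known < t))
        assert got == pytest.approx(best, abs=1e-12)

    def test_cross_check_against_sklearn(self, rng):
        sklearn = pytest.importorskip("sklearn.metrics")
        known, unknown = rng.random(50), rng.random(30) * 0.8
        y = np.r_[np.zeros(50), np.ones(30)]
        det = -np.r_[known, unknown]  # low confidence detects unknown
        assert auroc_unknown(known, unknown) == pytest.approx(
            sklearn.roc_auc_score(y, det), abs=1e-12
        )
        assert aupr_unknown(known, unknown) == pytest.approx(
            sklearn.average_precision_score(y, det), abs=1e-12
        )

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            auroc_unknown(np.array([]), np.array([0.1]))
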