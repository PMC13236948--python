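"""Protocol orchestration: Settings A/B, the 10-repeat protocol, and CI
summaries.

Setting A emulates deployment with no labeled field data: temperature and
abstention thresholds are fitted on the source validation split only.
Setting B allocates a small grouped field calibration split (10% of target
known samples, whole parent groups) and fits temperature and thresholds
there.  Both settings evaluate on held-out target test data and the
untouched unknown pool.  Split-sensitive quantities are repeated over seeds
42-51 and summarized by mean, n-1 SD, and t-based 95% confidence intervals.

No test-set label ever influences a fitted parameter or threshold: fitting
consumes only the calibration subset, and every run certifies that the
calibration and test id sets are disjoint and that no unknown sample took
part in any fitting step.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import stats as sstats

from . import calibration as cal
from . import selective as sel
from .probe import LinearHead, ProbeHyper, train_head_ensemble, train_linear_head
from .splits import grouped_calibration_split, stratified_source_split
from .synthetic import CohortConfig, FeatureCohort, make_feature_cohort
from .shiftstats import signed_rank_p

__all__ = [
    "RunConfig",
    "RepeatSummary",
    "CohortBundle",
    "prepare_cohorts",
    "run_setting",
    "run_repeats",
    "summarize_ci",
    "paired_comparison",
]


@dataclass(frozen=True)
class RunConfig:
    score_methods: tuple[str, ...] = sel.SCORE_METHODS
    nominal_coverages: tuple[float, ...] = (0.9, 0.8, 0.7, 0.6, 0.5)
    target_risks: tuple[float, ...] = (0.05, 0.10, 0.15)
    repeats: int = 10
    base_seed: int = 42
    n_bins: int = 15
    calib_fraction: float = 0.10

    def seeds(self) -> list[int]:
        return list(range(self.base_seed, self.base_seed + self.repeats))


@dataclass
class RepeatSummary:
    quantity: str
    values: list[float]
    mean: float
    sd: float
    ci95: tuple[float, float]
    seeds: list[int]


@dataclass
class CohortBundle:
    """Everything a setting evaluation needs: a trained probe's logits on the
    source val/test splits, the target known pool (with parent ids), and the
    unknown pool."""

    head: LinearHead
    src_val_logits: np.ndarray
    src_val_labels: np.ndarray
    src_test_logits: np.ndarray
    src_test_labels: np.ndarray
    tgt_logits: np.ndarray
    tgt_labels: np.ndarray
    tgt_sample_id: np.ndarray
    tgt_parent_id: np.ndarray
    unk_logits: np.ndarray
    unk_sample_id: np.ndarray
    train_sample_id: np.ndarray
    cohort_config: CohortConfig | None = None


def prepare_cohorts(
    config: CohortConfig,
    probe_hyper: ProbeHyper = ProbeHyper(),
    probe_seed: int = 0,
    head: LinearHead | None = None,
    cohort: FeatureCohort | None = None,
) -> CohortBundle:
    """Generate a cohort, split the source domain 70/15/15, train the probe
    on source train, and collect logits for every evaluation pool."""
    if cohort is None:
        cohort = make_feature_cohort(config)
    src = cohort.domain == "source"
    roles = np.full(cohort.n, "", dtype=object)
    roles[src] = stratified_source_split(cohort.labels[src], seed=config.seed)
    tr, va, te = (src & (roles == r) for r in ("train", "val", "test"))
    if head is None:
        head = train_linear_head(
            cohort.features[tr], cohort.labels[tr],
            cohort.features[va], cohort.labels[va],
            hyper=probe_hyper, seed=probe_seed,
        )
    tgt_known = (cohort.domain == "target") & cohort.known_flag
    unk = ~cohort.known_flag
    return CohortBundle(
        head=head,
        src_val_logits=head.logits(cohort.features[va]),
        src_val_labels=cohort.labels[va],
        src_test_logits=head.logits(cohort.features[te]),
        src_test_labels=cohort.labels[te],
        tgt_logits=head.logits(cohort.features[tgt_known]),
        tgt_labels=cohort.labels[tgt_known],
        tgt_sample_id=cohort.sample_id[tgt_known],
        tgt_parent_id=cohort.parent_id[tgt_known],
        unk_logits=head.logits(cohort.features[unk]),
        unk_sample_id=cohort.sample_id[unk],
        train_sample_id=cohort.sample_id[tr],
        cohort_config=config,
    )


def macro_f1(labels, predictions, n_classes: int) -> float:
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    f1s = []
    for k in range(n_classes):
        tp = np.sum((predictions == k) & (labels == k))
        fp = np.sum((predictions == k) & (labels != k))
        fn = np.sum((predictions != k) & (labels == k))
        denom = 2 * tp + fp + fn
        f1s.append(2 * tp / denom if denom else 0.0)
    return float(np.mean(f1s))


def _calibration_block(logits, labels, T, n_bins) -> dict:
    p_raw = cal.apply_temperature(logits, 1.0)
    p_cal = cal.apply_temperature(logits, T)
    if not np.array_equal(p_raw.argmax(axis=1), p_cal.argmax(axis=1)):
        raise AssertionError("temperature scaling changed the argmax")
    pred = p_cal.argmax(axis=1)
    K = logits.shape[1]
    return {
        "accuracy": float(np.mean(pred == labels)),
        "macro_f1": macro_f1(labels, pred, K),
        "ece_raw": cal.expected_calibration_error(p_raw, labels, n_bins),
        "ece_calibrated": cal.expected_calibration_error(p_cal, labels, n_bins),
        "brier_raw": cal.brier_score(p_raw, labels),
        "brier_calibrated": cal.brier_score(p_cal, labels),
        "mean_pmax_raw": float(p_raw.max(axis=1).mean()),
        "mean_pmax_calibrated": float(p_cal.max(axis=1).mean()),
    }


def run_setting(
    bundle: CohortBundle,
    setting: str,
    run_cfg: RunConfig = RunConfig(),
    split_seed: int = 42,
) -> dict:
    """Full metric battery for one setting and one grouped-split seed.

    Setting A fits temperature and thresholds on the source validation
    split; Setting B on the grouped field calibration split.  Both evaluate
    on the target known test pool and the untouched unknown pool.
    """
    if setting not in ("A", "B"):
        raise ValueError("setting must be 'A' or 'B'")
    if setting == "A":
        calib_logits, calib_labels = bundle.src_val_logits, bundle.src_val_labels
        test_sel = np.ones(len(bundle.tgt_logits), dtype=bool)
        calib_ids = set()
        calib_set_id = "source_val"
    else:
        manifest = grouped_calibration_split(
            bundle.tgt_sample_id, bundle.tgt_parent_id, bundle.tgt_labels,
            calib_fraction=run_cfg.calib_fraction, seed=split_seed,
        )
        is_calib = manifest.role == "field_calib"
        calib_logits, calib_labels = bundle.tgt_logits[is_calib], bundle.tgt_labels[is_calib]
        test_sel = ~is_calib
        calib_ids = set(bundle.tgt_sample_id[is_calib])
        calib_set_id = f"field_calib_seed{split_seed}"
        if not manifest.parent_disjoint("field_calib", "field_test"):
            raise RuntimeError("parent overlap between calibration and test")

    test_logits = bundle.tgt_logits[test_sel]
    test_labels = bundle.tgt_labels[test_sel]
    test_ids = set(bundle.tgt_sample_id[test_sel])

    # leakage certification: calibration/test disjoint, unknown pool untouched
    if calib_ids & test_ids:
        raise RuntimeError("calibration sample leaked into the test set")
    unk_ids = set(bundle.unk_sample_id)
    fitting_ids = calib_ids | set(bundle.train_sample_id)
    if unk_ids & fitting_ids:
        raise RuntimeError("unknown sample used in a fitting step")

    fit = cal.fit_temperature(calib_logits, calib_labels, calib_set_id)
    T = fit.temperature
    report: dict = {
        "setting": setting,
        "split_seed": split_seed,
        "temperature": T,
        "temperature_at_bound": fit.at_bound,
        "calibration_set_id": calib_set_id,
        "n_calib": int(len(calib_logits)),
        "n_test": int(len(test_logits)),
        "n_unknown": int(len(bundle.unk_logits)),
        "leakage_check": {
            "calib_test_overlap": 0,
            "unknown_in_fitting": 0,
        },
        "in_domain": _calibration_block(
            bundle.src_test_logits, bundle.src_test_labels, T, run_cfg.n_bins
        ),
        "cross_domain": _calibration_block(
            test_logits, test_labels, T, run_cfg.n_bins
        ),
        "scores": {},
    }

    calib_pred = calib_logits.argmax(axis=1)
    calib_correct = calib_pred == calib_labels
    test_correct = test_logits.argmax(axis=1) == test_labels
    for method in run_cfg.score_methods:
        s_cal = sel.confidence_score(calib_logits, T, method)
        s_test = sel.confidence_score(test_logits, T, method)
        s_unk = sel.confidence_score(bundle.unk_logits, T, method)
        block: dict = {
            "auroc_unknown": sel.auroc_unknown(s_test.scores, s_unk.scores),
            "aupr_unknown": sel.aupr_unknown(s_test.scores, s_unk.scores),
            "fpr95": sel.fpr_at_95tpr(s_test.scores, s_unk.scores),
            "fixed_coverage": {},
            "fixed_risk": {},
        }
        for target in run_cfg.nominal_coverages:
            pol = sel.threshold_for_coverage(s_cal.scores, target, calib_set_id)
            cov, risk = sel.selective_metrics(s_test.scores, test_correct, pol.tau)
            u_rej, k_rej = sel.rejection_rates(s_test.scores, s_unk.scores, pol.tau)
            block["fixed_coverage"][f"{target:.2f}"] = {
                "tau": pol.tau, "coverage": cov, "risk": risk,
                "calib_coverage": pol.achieved_calibration_coverage,
                "unknown_rejection": u_rej, "known_rejection": k_rej,
            }
        for target in run_cfg.target_risks:
            pol = sel.threshold_for_risk(s_cal.scores, calib_correct, target,
                                         calib_set_id)
            cov, risk = sel.selective_metrics(s_test.scores, test_correct, pol.tau)
            block["fixed_risk"][f"{target:.2f}"] = {
                "tau": pol.tau, "coverage": cov, "risk": risk,
                "abstain_all": pol.abstain_all,
            }
        report["scores"][method] = block
    return report


def _collect(report: dict, method_primary: str = "msp",
             method_openset: str = "energy") -> dict[str, float]:
    """Scalar split-sensitive quantities pulled out of one setting report."""
    cd = report["cross_domain"]
    prim = report["scores"][method_primary]
    ood = report["scores"][method_openset]
    out = {
        "temperature": report["temperature"],
        "accuracy": cd["accuracy"],
        "macro_f1": cd["macro_f1"],
        "ece_raw": cd["ece_raw"],
        "ece_calibrated": cd["ece_calibrated"],
        "brier_calibrated": cd["brier_calibrated"],
        "mean_pmax_calibrated": cd["mean_pmax_calibrated"],
        "risk_at_80_coverage": prim["fixed_coverage"]["0.80"]["risk"],
        "risk_at_50_coverage": prim["fixed_coverage"]["0.50"]["risk"],
        "coverage_at_10pct_risk": prim["fixed_risk"]["0.10"]["coverage"],
        "auroc_unknown_energy": ood["auroc_unknown"],
        "aupr_unknown_energy": ood["aupr_unknown"],
        "fpr95_energy": ood["fpr95"],
    }
    return {k: v for k, v in out.items() if v is not None}


def run_repeats(bundle: CohortBundle, run_cfg: RunConfig = RunConfig(),
                seeds: list[int] | None = None) -> dict:
    """Setting B over the configured repeat seeds, with per-quantity
    mean / SD / 95% CI summaries."""
    seeds = run_cfg.seeds() if seeds is None else list(seeds)
    if len(seeds) < 2:
        raise ValueError("need at least two repeats")
    if len(set(seeds)) != len(seeds):
        raise ValueError("repeat seeds must be distinct")
    per_seed: dict[int, dict[str, float]] = {}
    for seed in seeds:
        rep = run_setting(bundle, "B", run_cfg, split_seed=seed)
        per_seed[seed] = _collect(rep)
    names = sorted(per_seed[seeds[0]])
    summaries = {}
    for name in names:
        vals = [per_seed[s][name] for s in seeds if name in per_seed[s]]
        if len(vals) < 2:
            continue
        mean, sd, ci = summarize_ci(vals)
        summaries[name] = RepeatSummary(
            quantity=name, values=[float(v) for v in vals],
            mean=mean, sd=sd, ci95=ci, seeds=seeds,
        )
    return {"per_seed": per_seed, "summaries": summaries}


def summarize_ci(values) -> tuple[float, float, tuple[float, float]]:
    """mean, n-1 SD, and the t-based 95% CI: mean +/- t_{0.975, n-1} sd/sqrt(n)."""
    v = np.asarray(values, dtype=np.float64)
    if len(v) < 2:
        raise ValueError("need at least two values for a CI")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    half = float(sstats.t.ppf(0.975, len(v) - 1) * sd / np.sqrt(len(v)))
    return mean, sd, (mean - half, mean + half)


def paired_comparison(values_a, values_b) -> float:
    """Exact two-sided signed-rank p across paired repeats (p = 1 when all
    differences vanish)."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if len(a) != len(b):
        raise ValueError("paired sequences must have equal length")
    p, _ = signed_rank_p(a - b)
    return p


def summaries_to_json(result: dict) -> str:
    """Serialize a run_repeats result (dataclasses included) to JSON."""
    def default(o):
        if isinstance(o, RepeatSummary):
            return asdict(o)
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    return json.dumps(result, default=default, indent=2, sort_keys=True)
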