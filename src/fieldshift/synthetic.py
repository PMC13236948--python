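"""Synthetic cohorts with the statistical structure of a controlled-to-field study.

The real study trains on controlled single-leaf imagery (the *source* domain)
and deploys on heterogeneous field photographs (the *target* domain).  This
module emulates the pieces of that setting that the downstream reliability
analysis actually consumes:

* class-conditional Gaussian feature clusters per domain, with a controllable
  per-class mean shift and covariance inflation between source and target;
* an unknown-class pool drawn from Gaussians whose means lie outside the span
  of the known classes, absent from all training;
* parent-group structure over target samples (each field crop descends from a
  parent photograph);
* logit cohorts whose labels are sampled from a softened softmax at a known
  ground-truth temperature, so temperature recovery is testable;
* small RGB image ensembles where the target domain adds high-saturation
  distractors and border-concentrated texture, driving the image descriptors
  the shift analysis measures.

Every generator is a pure function of its config and seed: the same inputs
yield bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "CohortConfig",
    "FeatureCohort",
    "LogitCohort",
    "make_feature_cohort",
    "make_logit_cohort",
    "make_image_cohort",
    "make_heatmap",
    "write_manifest",
    "write_image_cohort",
]


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic feature cohort.

    Defaults mirror the study scale: 21 shared known classes, a 7-category
    unknown pool of 490 samples, and one crop per parent photograph.
    """

    n_known_classes: int = 21
    n_unknown_classes: int = 7
    samples_per_class_source: int = 150
    samples_per_class_target: int = 99
    feature_dim: int = 32
    class_sep: float = 5.0
    shift_mean: float = 6.0
    shift_common_frac: float = 0.6
    shift_cov_scale: float = 2.0
    unknown_pool_size: int = 490
    unknown_radius_factor: float = 2.5
    crops_per_parent: int = 1
    imbalance: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_known_classes < 2:
            raise ValueError("need at least two known classes")
        if self.n_unknown_classes < 0 or self.unknown_pool_size < 0:
            raise ValueError("unknown counts must be non-negative")
        if self.samples_per_class_source <= 0 or self.samples_per_class_target <= 0:
            raise ValueError("samples per class must be positive")
        if self.feature_dim <= 0:
            raise ValueError("feature_dim must be positive")
        if self.feature_dim < self.n_known_classes + self.n_unknown_classes:
            raise ValueError(
                "feature_dim must be >= n_known_classes + n_unknown_classes "
                "so class and unknown means can occupy disjoint directions"
            )
        if self.shift_mean < 0:
            raise ValueError("shift_mean must be non-negative")
        if self.shift_cov_scale < 1.0:
            raise ValueError("shift_cov_scale must be >= 1")
        if self.crops_per_parent < 1:
            raise ValueError("crops_per_parent must be >= 1")
        if not 0.0 <= self.shift_common_frac <= 1.0:
            raise ValueError("shift_common_frac must lie in [0, 1]")
        if not 0.0 <= self.imbalance < 1.0:
            raise ValueError("imbalance must lie in [0, 1)")


@dataclass
class FeatureCohort:
    """Per-sample feature vectors plus the metadata the protocol needs.

    ``labels`` uses the sentinel -1 for unknown-class samples.  ``parent_id``
    is non-empty only for target-domain samples (field crops descend from a
    parent photograph); source samples carry the empty string.
    """

    features: np.ndarray
    labels: np.ndarray
    sample_id: np.ndarray
    parent_id: np.ndarray
    domain: np.ndarray
    known_flag: np.ndarray
    config: CohortConfig | None = None

    def __post_init__(self) -> None:
        n = len(self.features)
        for name in ("labels", "sample_id", "parent_id", "domain", "known_flag"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name!r} length mismatch")
        if np.any(self.labels[~self.known_flag] != -1):
            raise ValueError("unknown samples must carry the sentinel label -1")
        tgt = self.domain == "target"
        if np.any(self.parent_id[tgt] == ""):
            raise ValueError("every target sample needs a parent_id")

    def mask(self, sel: np.ndarray) -> "FeatureCohort":
        return FeatureCohort(
            self.features[sel], self.labels[sel], self.sample_id[sel],
            self.parent_id[sel], self.domain[sel], self.known_flag[sel],
            self.config,
        )

    @property
    def n(self) -> int:
        return len(self.features)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "parent_id": self.parent_id,
                "label": self.labels,
                "domain": self.domain,
                "known_flag": self.known_flag,
            }
        )


@dataclass
class LogitCohort:
    """Raw logit vectors with labels sampled at a known temperature."""

    logits: np.ndarray
    labels: np.ndarray
    true_temperature: float | None = None
    sample_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.logits.ndim != 2 or self.logits.shape[1] < 2:
            raise ValueError("logits must be n x K with K >= 2")
        if len(self.labels) != len(self.logits):
            raise ValueError("labels length mismatch")
        if self.true_temperature is not None and self.true_temperature <= 0:
            raise ValueError("true_temperature must be positive")


def _class_geometry(config: CohortConfig, rng: np.random.Generator):
    """Seeded class/unknown means and per-class shift directions.

    Known-class means sit on scaled random orthonormal directions (so classes
    are separable at the documented separation); unknown means occupy the
    orthogonal complement at ``unknown_radius_factor`` times the known radius,
    making the open-set task well-posed but not trivial.
    """
    d = config.feature_dim
    K, U = config.n_known_classes, config.n_unknown_classes
    q, _ = np.linalg.qr(rng.standard_normal((d, d)))
    known_means = config.class_sep * q[:, :K].T
    unknown_means = (
        config.unknown_radius_factor * config.class_sep * q[:, K : K + U].T
    )
    # Heterogeneous per-class shift: a shared domain direction mixed with a
    # per-class idiosyncratic one, each drawn once per cohort.  Both live in
    # the span of the known class means: a shift that moves classes toward
    # one another is what collapses cross-domain accuracy, whereas a shift
    # into unused feature directions would leave the probe untouched.
    span = q[:, :K]
    g = span @ rng.standard_normal(K)
    g /= np.linalg.norm(g)
    deltas = np.empty((K, d))
    lam = config.shift_common_frac
    for k in range(K):
        e = span @ rng.standard_normal(K)
        e /= np.linalg.norm(e)
        v = lam * g + (1.0 - lam) * e
        v /= np.linalg.norm(v)
        deltas[k] = config.shift_mean * v
    return known_means, unknown_means, deltas


def _class_counts(base: int, K: int, imbalance: float, rng: np.random.Generator):
    if imbalance == 0.0:
        return np.full(K, base, dtype=int)
    # Linearly tilted class sizes; the knob exists because the real corpora's
    # imbalance profile is unspecified, balanced is the default condition.
    w = 1.0 + imbalance * np.linspace(-1.0, 1.0, K)
    counts = np.maximum(2, np.round(base * w / w.mean()).astype(int))
    return counts


def make_feature_cohort(config: CohortConfig) -> FeatureCohort:
    """Generate source, target-known and unknown feature samples.

    Source samples are drawn from N(mu_k, I); target known samples from
    N(mu_k + delta_k, shift_cov_scale * I) with ||delta_k|| = shift_mean;
    unknown samples from well-separated extra Gaussians.  Target samples are
    organised into parent groups of ``crops_per_parent`` crops each.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    known_means, unknown_means, deltas = _class_geometry(config, rng)
    d = config.feature_dim
    K = config.n_known_classes

    feats, labels, sids, pids, doms, known = [], [], [], [], [], []

    src_counts = _class_counts(
        config.samples_per_class_source, K, config.imbalance, rng
    )
    for k in range(K):
        n_k = src_counts[k]
        feats.append(known_means[k] + rng.standard_normal((n_k, d)))
        labels.append(np.full(n_k, k))
        sids.extend(f"src_c{k:02d}_{i:04d}" for i in range(n_k))
        pids.extend([""] * n_k)
        doms.extend(["source"] * n_k)
        known.extend([True] * n_k)

    tgt_counts = _class_counts(
        config.samples_per_class_target, K, config.imbalance, rng
    )
    sd = math.sqrt(config.shift_cov_scale)
    parent_counter = 0
    for k in range(K):
        n_k = tgt_counts[k]
        feats.append(known_means[k] + deltas[k] + sd * rng.standard_normal((n_k, d)))
        labels.append(np.full(n_k, k))
        sids.extend(f"tgt_c{k:02d}_{i:04d}" for i in range(n_k))
        for i in range(n_k):
            pids.append(f"parent_{parent_counter + i // config.crops_per_parent:05d}")
        parent_counter += -(-n_k // config.crops_per_parent)
        doms.extend(["target"] * n_k)
        known.extend([True] * n_k)

    n_unk = config.unknown_pool_size if config.n_unknown_classes > 0 else 0
    if n_unk:
        assign = rng.integers(0, config.n_unknown_classes, size=n_unk)
        for i in range(n_unk):
            feats.append(
                unknown_means[assign[i]][None, :]
                + sd * rng.standard_normal((1, d))
            )
            labels.append(np.array([-1]))
            sids.append(f"unk_{i:04d}")
            pids.append(f"parent_unk_{i:05d}")
            doms.append("target")
            known.append(False)

    return FeatureCohort(
        features=np.vstack(feats),
        labels=np.concatenate(labels).astype(int),
        sample_id=np.asarray(sids, dtype=object),
        parent_id=np.asarray(pids, dtype=object),
        domain=np.asarray(doms, dtype=object),
        known_flag=np.asarray(known, dtype=bool),
        config=config,
    )


def make_logit_cohort(
    n: int,
    K: int,
    true_temperature: float,
    margin: float = 2.0,
    seed: int = 0,
) -> LogitCohort:
    """Draw raw logits with a class-dependent margin, then sample labels
    from softmax(z / true_temperature).

    The recorded temperature is recoverable by NLL minimization, which is the
    contract temperature-scaling tests rely on.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if K < 2:
        raise ValueError("K must be >= 2")
    if true_temperature <= 0:
        raise ValueError("true_temperature must be positive")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, K))
    intended = rng.integers(0, K, size=n)
    z[np.arange(n), intended] += margin
    zs = z / true_temperature
    zs -= zs.max(axis=1, keepdims=True)
    p = np.exp(zs)
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random((n, 1))
    labels = (p.cumsum(axis=1) < u).sum(axis=1).clip(0, K - 1)
    sid = np.asarray([f"logit_{i:06d}" for i in range(n)], dtype=object)
    return LogitCohort(z, labels.astype(int), true_temperature, sid)


# ---------------------------------------------------------------------------
# image cohorts


def _hsv_to_rgb(h: float, s: float, v: float) -> np.ndarray:
    i = int(h * 6.0) % 6
    f = h * 6.0 - int(h * 6.0)
    p, q, t = v * (1 - s), v * (1 - f * s), v * (1 - (1 - f) * s)
    return np.array(
        [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)][i]
    )


def _ellipse_mask(size: int, cx, cy, rx, ry) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0


def _base_leaf_image(size, label, n_classes, rng):
    """Uniform low-saturation background plus one smooth elliptical foreground."""
    bg_v = 0.55 + 0.1 * rng.random()
    bg = _hsv_to_rgb(0.25, 0.08, bg_v)
    img = np.broadcast_to(bg, (size, size, 3)).copy()
    img += 0.01 * rng.standard_normal(img.shape)
    hue = 0.20 + 0.45 * (label / max(n_classes - 1, 1))
    fg = _hsv_to_rgb(hue, 0.55, 0.6 + 0.1 * rng.random())
    cx = size / 2 + rng.uniform(-0.05, 0.05) * size
    cy = size / 2 + rng.uniform(-0.05, 0.05) * size
    rx = size * rng.uniform(0.24, 0.32)
    ry = size * rng.uniform(0.24, 0.32)
    mask = _ellipse_mask(size, cx, cy, rx, ry)
    img[mask] = fg + 0.02 * rng.standard_normal((mask.sum(), 3))
    return np.clip(img, 0.0, 1.0)


def _add_clutter(img, clutter_level, rng):
    """Field-style degradation: saturated distractors + border texture."""
    size = img.shape[0]
    n_distract = int(round(clutter_level * 6))
    for _ in range(n_distract):
        hue = rng.uniform(0.0, 1.0)
        color = _hsv_to_rgb(hue, 0.9, 0.8)
        cx, cy = rng.uniform(0, size, 2)
        r = size * rng.uniform(0.04, 0.10)
        mask = _ellipse_mask(size, cx, cy, r, r)
        img[mask] = color
    if clutter_level > 0:
        b = max(1, int(round(0.2 * size)))
        strip = np.zeros((size, size), dtype=bool)
        strip[:b, :] = strip[-b:, :] = True
        strip[:, :b] = strip[:, -b:] = True
        noise = clutter_level * 0.35 * rng.standard_normal((strip.sum(), 3))
        img[strip] = np.clip(img[strip] + noise, 0.0, 1.0)
        # saturated speckle in the border, emulating out-of-focus canopy
        sat_boost = clutter_level * 0.5 * rng.random(strip.sum())
        hsv_like = img[strip]
        img[strip] = np.clip(
            hsv_like * (1 - sat_boost[:, None])
            + sat_boost[:, None] * np.array([0.1, 0.8, 0.1]),
            0.0,
            1.0,
        )
    return np.clip(img, 0.0, 1.0)


def make_image_cohort(
    n_per_domain: int,
    image_size: int = 64,
    clutter_level: float = 0.8,
    n_classes: int = 21,
    seed: int = 0,
) -> dict:
    """Labeled RGB image ensembles for both domains, pixel values in [0, 1].

    Source images are a single smooth elliptical foreground on a uniform
    low-saturation background; target images add ``clutter_level``-controlled
    high-saturation distractor shapes and border-concentrated texture.  At
    clutter_level 0 the two domains are statistically identical.
    """
    if image_size < 32:
        raise ValueError("image_size must be >= 32")
    if not 0.0 <= clutter_level <= 1.0:
        raise ValueError("clutter_level must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = {}
    for domain in ("source", "target"):
        images, labels = [], []
        for k in range(n_classes):
            for _ in range(n_per_domain):
                img = _base_leaf_image(image_size, k, n_classes, rng)
                if domain == "target":
                    img = _add_clutter(img, clutter_level, rng)
                images.append(img)
                labels.append(k)
        out[domain] = (np.stack(images), np.asarray(labels))
    return out


def make_heatmap(size: int, center: tuple[float, float], sigma: float) -> np.ndarray:
    """Non-negative Gaussian-blob attention map, for border-mass analysis."""
    yy, xx = np.mgrid[0:size, 0:size]
    cy, cx = center
    h = np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sigma**2)))
    return h


# ---------------------------------------------------------------------------
# persistence


def write_manifest(cohort: FeatureCohort, path: str | Path,
                   roles: dict[str, str] | None = None) -> pd.DataFrame:
    """Write the manifest CSV (sample_id, parent_id, label, domain, known_flag, role)."""
    df = cohort.to_frame()
    df["role"] = [
        (roles or {}).get(s, "unassigned") for s in cohort.sample_id
    ]
    df.to_csv(path, index=False)
    return df


def write_image_cohort(cohort: dict, out_dir: str | Path) -> list[Path]:
    """Save an image cohort as 8-bit RGB PNGs in per-class directories."""
    out_dir = Path(out_dir)
    written = []
    for domain, (images, labels) in cohort.items():
        for i, (img, lab) in enumerate(zip(images, labels)):
            d = out_dir / domain / f"class_{lab:02d}"
            d.mkdir(parents=True, exist_ok=True)
            arr = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
            p = d / f"img_{i:04d}.png"
            Image.fromarray(arr).save(p)
            written.append(p)
    return written
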