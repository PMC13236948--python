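"""Model-free quantification of visual domain shift.

Seventeen low-level descriptors summarize each image's color distribution,
spatial frequency content, texture, and a foreground-occupancy proxy.  For
each descriptor, image values are averaged within (class, domain) cells and
the paired source/target difference across classes is tested with an exact
Wilcoxon signed-rank test and summarized with a paired Cohen's d; the
descriptor family is Bonferroni-corrected.  A border-mass ratio quantifies
how much of an attention heatmap falls in the outer strip of the image.

Concrete descriptor formulas (constants in module config below): edge
density is the fraction of pixels whose Sobel gradient magnitude exceeds 0.1
on the [0, 1] grayscale; the border region is the outer 20% strip of width
and height; gray entropy is the Shannon entropy (nats) of the 256-bin gray
histogram; LBP entropy is the entropy of the uniform 8-neighbor radius-1
local-binary-pattern code histogram; color variance is the mean of the three
per-channel RGB variances; foreground occupancy is the fraction of pixels
with saturation > 0.25 or gradient magnitude > 0.1; hue dispersion is the
circular standard deviation of hue; edge-orientation entropy is the entropy
of an 8-bin histogram of folded gradient orientations over above-threshold
pixels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.color import rgb2gray, rgb2hsv
from skimage.feature import local_binary_pattern
from skimage.filters import laplace, sobel_h, sobel_v

__all__ = [
    "DESCRIPTOR_NAMES",
    "ShiftTestResult",
    "compute_descriptors",
    "class_domain_aggregate",
    "paired_shift_test",
    "signed_rank_p",
    "bonferroni_adjust",
    "shift_report",
    "border_mass_ratio",
]

EDGE_THRESHOLD = 0.1
SATURATION_THRESHOLD = 0.25
BORDER_FRACTION = 0.2
GRAY_BINS = 256
ORIENTATION_BINS = 8
LBP_POINTS, LBP_RADIUS = 8, 1

DESCRIPTOR_NAMES = (
    "mean_saturation", "var_saturation", "mean_value", "var_value",
    "mean_gray", "var_gray", "color_variance", "laplacian_variance",
    "sobel_edge_density", "border_edge_density", "center_edge_density",
    "gray_entropy", "lbp_entropy", "foreground_occupancy",
    "mean_hue_dispersion", "border_saturation_mean",
    "edge_orientation_entropy",
)


@dataclass
class ShiftTestResult:
    delta: float
    cohens_d: float
    p_raw: float
    exact: bool


def _hist_entropy(values: np.ndarray, bins, range_=None) -> float:
    counts, _ = np.histogram(values, bins=bins, range=range_)
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log(p)))


def _border_mask(h: int, w: int, frac: float = BORDER_FRACTION) -> np.ndarray:
    bh = max(1, int(round(frac * h)))
    bw = max(1, int(round(frac * w)))
    m = np.zeros((h, w), dtype=bool)
    m[:bh, :] = m[-bh:, :] = True
    m[:, :bw] = m[:, -bw:] = True
    return m


def compute_descriptors(image: np.ndarray) -> dict[str, float]:
    """All 17 descriptors for one RGB image with values in [0, 1]."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    if min(img.shape[:2]) < 16:
        raise ValueError("image min side must be >= 16")
    hsv = rgb2hsv(img)
    hue, sat, val = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    gray = rgb2gray(img)
    gy, gx = sobel_h(gray), sobel_v(gray)
    grad = np.hypot(gx, gy)
    edge = grad > EDGE_THRESHOLD
    border = _border_mask(*gray.shape)
    gray8 = np.clip(np.round(gray * 255.0), 0, 255).astype(np.uint8)
    # drop the radius-wide margin: border codes see out-of-image neighbors
    lbp = local_binary_pattern(gray8, LBP_POINTS, LBP_RADIUS, method="uniform")
    lbp = lbp[LBP_RADIUS:-LBP_RADIUS, LBP_RADIUS:-LBP_RADIUS]

    # circular std of hue (hue lives on the unit circle)
    ang = 2.0 * math.pi * hue
    R = float(np.hypot(np.cos(ang).mean(), np.sin(ang).mean()))
    circ_std = math.sqrt(max(0.0, -2.0 * math.log(max(R, 1e-300))))

    ori_pix = grad > EDGE_THRESHOLD
    if ori_pix.any():
        theta = np.arctan2(np.abs(gy[ori_pix]), np.abs(gx[ori_pix]))
        ori_entropy = _hist_entropy(theta, ORIENTATION_BINS, (0.0, math.pi / 2))
    else:
        ori_entropy = 0.0

    d = {
        "mean_saturation": float(sat.mean()),
        "var_saturation": float(sat.var(ddof=1)),
        "mean_value": float(val.mean()),
        "var_value": float(val.var(ddof=1)),
        "mean_gray": float(gray.mean()),
        "var_gray": float(gray.var(ddof=1)),
        "color_variance": float(np.mean([img[..., c].var(ddof=1) for c in range(3)])),
        "laplacian_variance": float(laplace(gray).var(ddof=1)),
        "sobel_edge_density": float(edge.mean()),
        "border_edge_density": float(edge[border].mean()),
        "center_edge_density": float(edge[~border].mean()),
        "gray_entropy": _hist_entropy(gray, GRAY_BINS, (0.0, 1.0)),
        "lbp_entropy": _hist_entropy(lbp, int(lbp.max()) + 1),
        "foreground_occupancy": float(
            ((sat > SATURATION_THRESHOLD) | (grad > EDGE_THRESHOLD)).mean()
        ),
        "mean_hue_dispersion": circ_std,
        "border_saturation_mean": float(sat[border].mean()),
        "edge_orientation_entropy": ori_entropy,
    }
    return d


def descriptor_table(images: np.ndarray) -> pd.DataFrame:
    """Stack compute_descriptors over a batch of images."""
    return pd.DataFrame([compute_descriptors(im) for im in images])


def class_domain_aggregate(descriptors: pd.DataFrame, labels, domains) -> pd.DataFrame:
    """Mean descriptor vector per (class, domain) cell.

    Classes missing from either domain are excluded with a warning, since a
    paired test needs both sides.
    """
    df = descriptors.copy()
    df["_label"] = np.asarray(labels)
    df["_domain"] = np.asarray(domains)
    agg = df.groupby(["_label", "_domain"], sort=True).mean()
    keep = []
    for k in agg.index.get_level_values(0).unique():
        doms = set(agg.loc[k].index)
        if doms >= {"source", "target"}:
            keep.append(k)
        else:
            warnings.warn(f"class {k} missing in one domain; excluded", RuntimeWarning)
    return agg.loc[keep]


def _exact_enumeration_p(ranks: np.ndarray, w_obs: float) -> float:
    """Two-sided exact signed-rank p by full 2^n sign enumeration (midranks
    allowed).  Feasible for n <= ~20; used for tied small samples."""
    n = len(ranks)
    le = ge = 0
    total = 1 << n
    for mask in range(total):
        w = 0.0
        for i in range(n):
            if mask >> i & 1:
                w += ranks[i]
        if w <= w_obs + 1e-12:
            le += 1
        if w >= w_obs - 1e-12:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)


def signed_rank_p(diffs) -> tuple[float, bool]:
    """Two-sided Wilcoxon signed-rank p for paired differences.

    Zeros are dropped (Wilcoxon convention).  Exact distribution for untied
    n <= 25; tied samples use full sign enumeration for n <= 12 and the
    tie-corrected normal approximation otherwise.  Returns (p, exact_flag).
    """
    d = np.asarray(diffs, dtype=np.float64)
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return 1.0, True
    absd = np.abs(d)
    tied = len(np.unique(absd)) < n
    if not tied and n <= 25:
        res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                             method="exact")
        return float(res.pvalue), True
    if tied and n <= 12:
        ranks = stats.rankdata(absd)
        w_obs = float(ranks[d > 0].sum())
        return _exact_enumeration_p(ranks, w_obs), True
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                         method="approx")
    return float(res.pvalue), False


def paired_shift_test(source_class_means, target_class_means) -> ShiftTestResult:
    """delta, paired Cohen's d, and exact two-sided signed-rank p for the
    class-paired source/target difference of one descriptor."""
    s = np.asarray(source_class_means, dtype=np.float64)
    t = np.asarray(target_class_means, dtype=np.float64)
    if len(s) != len(t):
        raise ValueError("class-mean sequences must be paired")
    if len(s) < 5:
        raise ValueError("need at least 5 paired classes")
    diff = t - s
    sd = diff.std(ddof=1)
    if sd == 0.0:
        warnings.warn("zero-variance differences; Cohen's d is infinite",
                      RuntimeWarning)
        d_eff = math.copysign(math.inf, diff.mean()) if diff.mean() != 0 else 0.0
    else:
        d_eff = float(diff.mean() / sd)
    p, exact = signed_rank_p(diff)
    return ShiftTestResult(delta=float(diff.mean()), cohens_d=d_eff,
                           p_raw=p, exact=exact)


def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """p_adj = min(1, m * p) with m the size of the descriptor family."""
    p = np.asarray(p_values, dtype=np.float64)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p values must lie in (0, 1]")
    m = len(p) if m is None else m
    if m < len(p):
        raise ValueError("m must be at least the family size")
    return np.minimum(1.0, m * p)


def shift_report(descriptors: pd.DataFrame, labels, domains,
                 alpha: float = 0.05) -> pd.DataFrame:
    """Per-descriptor paired class-mean test with Bonferroni correction.

    Columns mirror the study's shift table: metric, cohens_d, delta, p_raw,
    p_bonferroni, significant.
    """
    agg = class_domain_aggregate(descriptors, labels, domains)
    src = agg.xs("source", level="_domain")
    tgt = agg.xs("target", level="_domain")
    rows = []
    for name in descriptors.columns:
        r = paired_shift_test(src[name].to_numpy(), tgt[name].to_numpy())
        rows.append({"metric": name, "cohens_d": r.cohens_d, "delta": r.delta,
                     "p_raw": r.p_raw, "exact": r.exact})
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = bonferroni_adjust(out["p_raw"].to_numpy(), len(out))
    out["significant"] = out["p_bonferroni"] < alpha
    return out.sort_values("cohens_d", ascending=False, ignore_index=True)


def border_mass_ratio(heatmap: np.ndarray, strip_fraction: float = 0.2) -> float:
    """Fraction of heatmap mass in the outer strip of width/height."""
    h = np.asarray(heatmap, dtype=np.float64)
    if h.ndim != 2:
        raise ValueError("heatmap must be 2-D")
    if np.any(h < 0):
        raise ValueError("heatmap must be non-negative")
    total = h.sum()
    if total == 0:
        raise ValueError("all-zero heatmap has no mass to apportion")
    mask = _border_mask(*h.shape, frac=strip_fraction)
    return float(h[mask].sum() / total)
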