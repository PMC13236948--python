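# Methods

## The protocol being characterized

The package evaluates a classifier trained on a *source* domain (controlled
imagery) and deployed on a *target* domain (field imagery) along four axes:
accuracy, probability calibration, selective prediction, and unknown-class
rejection. Two calibration regimes are compared. Under **Setting A** no
labeled target data exists: the temperature and all abstention thresholds
are fitted on the source validation split and transferred. Under
**Setting B** a small grouped calibration split (10% of target known
samples, whole parent-image groups) supplies field statistics. In both
settings the target test pool and the unknown pool are untouched by any
fitting step; every run certifies that the calibration and test sample-id
sets are disjoint and that no unknown sample entered training or
calibration. Split-sensitive quantities are repeated over ten grouped
splits (seeds 42–51) and summarized by mean, n−1 SD, and a t-based 95% CI
(t rather than normal: conservative at n = 10, and the choice is recorded
in the report schema).

## Synthetic cohorts

The generators in `fieldshift.synthetic` emulate the statistical structure
this analysis consumes, not the appearance of real data.

**Feature cohorts.** Known-class means `μ_k = s·q_k` sit on random
orthonormal directions `q_k` (seeded QR of a Gaussian matrix) scaled by the
class separation `s` (default 5.0). With unit within-class covariance the
nearest-mean ceiling is `1 − 20·Φ(−s/√2) ≈ 0.996` for 21 classes, i.e. the
near-ceiling in-domain regime of a frozen-feature probe on controlled
imagery. Target known samples are drawn from
`N(μ_k + δ_k, c·I)` with covariance inflation `c = 2.0` and a per-class
shift `δ_k` of norm 6.0 (≈ 0.85 of the pairwise class-mean distance — a
severe shift that collapses accuracy by tens of points without destroying
it). Each `δ_k` mixes a shared domain direction with a per-class
idiosyncratic one (`shift_common_frac = 0.6`), both drawn once per cohort
*inside the span of the class means*: a shift toward other classes is what
produces confusion, and the shared component is what channel-wise moment
matching can remove — mirroring a global saturation/illumination shift
plus class-specific degradation. Unknown-class means occupy the orthogonal
complement at 2.5× the known radius: far enough that the open-set task is
well-posed, close enough that softmax confidences still overlap. Defaults
follow the study scale: 21 known classes, a 7-category unknown pool of 490
samples, ~2080 target known crops, one crop per parent (a `crops_per_parent`
knob generalizes this), balanced classes with an imbalance knob (the real
corpora's imbalance profile is unspecified).

**Logit cohorts.** Raw logits are standard normal with a margin added to a
random intended class; labels are then sampled from `softmax(z/T_true)`.
This makes `T_true` identifiable by NLL minimization, which is exactly the
property temperature-recovery tests need.

**Image cohorts.** Source images are one smooth low-frequency ellipse on a
uniform low-saturation background (hue varies by class). Target images add
`clutter_level`-controlled high-saturation distractor ellipses and
border-concentrated noise/saturation texture. At `clutter_level = 0` the
two domains are generated by the identical process, giving an exact null
for the type-I-control check. What the image generator does *not* emulate:
photorealistic leaves or lesions, correlated backgrounds across images of a
class, localization error, or illumination fields — so a passing shift
analysis demonstrates the statistics pipeline, not descriptor sensitivity
on real photographs.

## Models and numerics

**Linear probe.** Multinomial logistic regression trained by full-batch
gradient descent on the cross-entropy plus an L2 penalty (weight decay
0.01), early stopping with patience 5 on validation accuracy, and the
best-validation checkpoint retained. Probe-scale schedule constants (lr
0.5, ≤300 epochs, init std 0.5) were chosen for the convex objective at
these feature scales. Training is deterministic per seed. Head ensembles
re-run the identical fit from M = 5 initialization seeds; because the
regularized objective has a unique optimum, member diversity comes from
finite training and expresses itself mostly in directions weakly
constrained by the source data — which is why disagreement (epistemic MI)
concentrates on the out-of-span unknown pool.

**Temperature fitting.** A single bounded parameter is fitted by
Brent-style bounded scalar minimization of the calibration NLL on
T ∈ [0.01, 1000] to 1e-6 (identical optimum to a quasi-Newton fit; the
optimizer trace is retained for audit). If the NLL plateaus or decreases
monotonically into a bound (e.g. every calibration prediction correct with
huge margins), the bound is returned with an `at_bound` flag. Scaled
argmax equality with the raw argmax is asserted on every evaluation run.

**Binning.** Reliability bins are equal-width on [0, 1], last bin
right-closed, others right-open; empty bins contribute nothing to ECE, and
recomputing ECE from the reliability table reproduces the scalar
bit-exactly because the scalar is defined through the table.

**Thresholds.** Candidate thresholds are the distinct observed score
values (plus a +∞ sentinel). Fixed-coverage picks the largest τ whose
calibration coverage reaches the target, so achieved coverage can exceed
the nominal level under ties. Fixed-risk maximizes calibration coverage
subject to calibration risk ≤ target; when no candidate is feasible the
policy is the abstain-all sentinel (τ = +∞). Selection uses `s ≥ τ`,
rejection `s < τ`; selective risk at zero coverage is reported as
undefined, never 0.

**Open-set metrics.** The detector statistic is the negated confidence
score (larger score = more in-distribution). AUROC is the Mann–Whitney
probability with ties counted ½; AUPR uses step interpolation
(Σ precision·Δrecall over distinct thresholds); FPR95 is the known-class
flag rate at the least conservative threshold with unknown TPR ≥ 0.95, a
step function with no interpolation.

**Signed-rank tests.** Zeros are dropped. Untied samples with n ≤ 25 use
the exact null distribution (the study's class-paired tests have n = 21,
where the two-sided floor is 2/2²¹ = 9.54e-7). Tied samples use a full
2ⁿ midrank sign enumeration for n ≤ 12 and the tie-corrected normal
approximation beyond that, flagged as non-exact in the output. Cohen's *d*
is the paired `mean(diff)/sd(diff)` with n−1 normalization (n−1 is used
for every variance in the package). Bonferroni adjustment is
`min(1, m·p)` with m = 17 descriptors.

**Descriptors.** The 17 formulas are fixed, auditable choices: edge
density = fraction of pixels with Sobel gradient magnitude > 0.1 on the
[0,1] grayscale; border region = outer 20% strip of width and height; gray
entropy = Shannon entropy of the 256-bin histogram; LBP entropy = entropy
of the uniform 8-neighbor radius-1 code histogram (the radius-wide image
margin is excluded, since border codes see out-of-image neighbors);
foreground occupancy = saturation > 0.25 OR gradient > 0.1; hue dispersion
= circular SD of hue; orientation entropy = 8-bin histogram of folded
gradient orientations over above-threshold pixels. All 17 are invariant to
horizontal/vertical flips by construction. Constants live in module-level
config.

**Epsilons.** Probability clamps for logs use 1e-12 (cross-entropy,
ensemble pseudo-logits) and near-zero channel SDs in moment matching fall
back to 1e-12, each with a warning. Epistemic MI is computed as the
difference `H[p̄] − E[H]`, so the additive identity holds exactly and MI
can be negative only at floating-point scale (≥ −1e-12).

## Design choices where the design was open

- **Grouped stratification.** Per class, parent groups are shuffled by
  seed and added to the calibration side until the class calibration
  fraction first reaches the target. With one crop per parent this reduces
  to plain greedy stratification, giving per-class fractions in
  [0.09, 0.11] at the default cohort sizes.
- **Ensemble pseudo-logits** are `log p̄`: the unique choice whose T = 1
  softmax reproduces the ensemble predictive distribution. Scores for the
  ensemble path use the mean probabilities; the decomposition always uses
  raw member outputs.
- **Entropies in nats** throughout; the normalized-entropy confidence
  divides by log K and is therefore base-free.
- **Assignment tie-breaks** between equidistant sources resolve to the
  lowest index (logged). Unmatched crops are dropped, never imputed.
- **Category alignment** between label vocabularies is a user-supplied
  two-column mapping table, not hard-coded.

## Problem sizes

Default analysis and test runs use the 21-class cohort (3150 source / 2079
target-known / 490 unknown samples, 32-d features), 50 000-sample logit
cohorts for temperature recovery, and 48–64 px image cohorts with 2–4
images per class and domain; these sizes make every pipeline property
measurable while keeping a full run in seconds on one CPU.

## Known limitations

- The feature generator is Gaussian and homoscedastic within class;
  real penultimate-layer features are neither, so absolute metric values
  (e.g. the size of the calibrated ECE) are not comparable to real-data
  studies — only orderings and protocol properties are.
- With one crop per parent the grouped split is exercised but not
  stressed; `crops_per_parent > 1` covers the leakage-relevant case in
  tests.
- The tie-corrected normal approximation for large tied signed-rank
  samples is asymptotic; it is flagged in output and never used for the
  n = 21 class-paired analyses unless ties actually occur.
- Linear-head ensembles capture initialization sensitivity only; their
  epistemic MI is a disagreement diagnostic, not a full model-uncertainty
  measure.
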