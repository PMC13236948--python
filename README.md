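# fieldshift

Reliability characterization of image classifiers under controlled-to-field
domain shift.

Classifiers for leaf-disease diagnosis are typically trained on controlled
imagery (single centered leaves, uniform backgrounds) and deployed on
heterogeneous field photographs. Accuracy collapses under that shift — and,
worse, predicted confidence does not: the model keeps reporting high
probabilities for wrong answers, and it confidently labels crops and
diseases it has never seen. `fieldshift` implements the full evaluation
protocol needed to measure that reliability gap, for researchers who want to
report calibration, selective risk, and open-set behavior alongside
accuracy:

- **Calibration** — temperature scaling `p̂(T) = softmax(z/T)` with `T*`
  fitted by NLL minimization on a calibration split; reliability diagrams
  over M = 15 equal-width bins; ECE
  `Σ_m |B_m|/N · |acc(B_m) − conf(B_m)|` and the multiclass Brier score.
- **Selective prediction** — four confidence scores from the calibrated
  classifier (MSP `max_k p̂_k`, normalized-entropy confidence
  `1 − H(p̂)/log K`, top-two margin `p̂_(1) − p̂_(2)`, energy
  `log Σ_k exp(z_k/T)`); answer iff `s(x) ≥ τ`; coverage `φ(τ)` and
  selective risk `r(τ)`; fixed-coverage and fixed-risk threshold policies
  fitted on calibration data and transferred unchanged to test data.
- **Open-set scoring** — unknown-class detection by low confidence:
  AUROC, AUPR with unknowns as positives, FPR at 95% TPR, and
  unknown/known rejection rates.
- **Ensemble uncertainty** — member-mean predictive distribution
  `p̄ = (1/M) Σ_m p^(m)` and the decomposition
  `H[p̄] = E_m[H[p^(m)]] + MI` into aleatoric and epistemic parts.
- **Leakage-safe protocol** — parent-image reconstruction by Hungarian
  assignment on 32×32 thumbnails, stratified 70/15/15 source splits, and
  grouped field-calibration splits that keep every parent photograph's
  crops on one side (repeated over seeds 42–51 with t-based 95% CIs).
- **Shift quantification** — 17 image-level descriptors (saturation, edge
  densities, entropies, a foreground-occupancy proxy, …) compared across
  domains by class-paired exact Wilcoxon signed-rank tests with Cohen's *d*
  and Bonferroni correction, plus a heatmap border-mass ratio.

Real archives are replaced by a first-class synthetic-data module
(`fieldshift.synthetic`) that emulates the statistical structure the
analysis assumes: class-conditional Gaussian feature clusters with a
controllable source→target mean shift and covariance inflation, an unknown
pool absent from training, parent-group structure, logits with a known
ground-truth temperature, and paired image ensembles with controllable
clutter. Every generator is bit-reproducible from its config and seed.

## Worked example

The numbered drivers under `analysis/` run the study end to end and write
tables under `results/`. For example:

```bash
python analysis/03_probe_and_adaptation.py --seed 0
```

```
probe accuracy: in-domain 0.983, cross-domain 0.620 (gap 0.363)
moment matching lifts cross-domain accuracy to 0.799
```

The linear probe that classifies 98% of in-domain samples correctly loses
36 points on the shifted target domain; aligning source features to the
target's channel means and variances (estimated from the 10% grouped field
calibration split only) recovers a large part of the loss.

```bash
python analysis/04_calibration_and_selective.py --seed 0
```

```
Setting A: T=0.311  acc=0.6224  ece_raw=0.0974  ece_cal=0.2922  brier_cal=0.6465
Setting B: T=1.292  acc=0.6201  ece_raw=0.1000  ece_cal=0.0260  brier_cal=0.5048
```

Setting A (no labeled field data: temperature fitted on the source
validation split) mis-estimates the temperature and *worsens* cross-domain
ECE; Setting B (a small grouped field calibration split) brings calibrated
ECE down to 0.026. `analysis/05_ensemble_uncertainty.py` shows the
epistemic mutual information of a five-head ensemble averaging 0.20 nats on
shifted known-class samples but 0.76 nats on the unknown pool, and
`analysis/06_shift_statistics.py` reproduces the descriptor analysis: under
heavy clutter the border edge density, foreground occupancy, and mean
saturation all shift with the exact-Wilcoxon floor p = 9.54e-7 across 21
paired classes, while a clutter-free null cohort yields no
Bonferroni-significant descriptor.

## Layout

```
src/fieldshift/     library: synthetic, splits, probe, calibration,
                    selective, ensemble, shiftstats, reporting
analysis/           numbered narrative drivers (01 … 07)
tests/              pytest suite incl. oracle-equivalence and
                    end-to-end acceptance properties
scripts/            acceptance.py
docs/methods.md     models, assumptions, parameter choices, limitations
```
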