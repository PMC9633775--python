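# dyngrad

Arousal-dependent dynamic functional-connectivity gradients: a tested
Python implementation of the full analysis chain linking cortical
functional gradients to structural connectivity and neuromodulatory
receptor expression, exercised end-to-end on synthetic cohorts with known
ground truth.

## The problem

Resting-state fMRI connectivity can be compressed into a few *functional
gradients* — smooth spatial axes obtained by nonlinear embedding of the
region × region correlation matrix. Two questions drive this package:

1. **What shapes the gradients?** Structural wiring (retrograde-tracing
   connectivity) and the ascending neuromodulatory system (receptor
   expression similarity) both predict functional connectivity, but they
   overlap heavily; separating their unique contributions needs care.
2. **How do gradients move with arousal?** Frame-resolved dynamic
   connectivity, binned by an arousal index read out from pupil size or
   from the BOLD frames themselves, reveals arousal-dependent waxing and
   waning of gradient structure.

## The methods implemented

* **Gradients** — per-row top-10% thresholding of the FC matrix, the
  normalized-angle affinity `A_ij = 1 − arccos(cos θ_ij)/π`, diffusion-map
  embedding (α = 0.5, components scaled by λ/(1−λ), explained variance
  λ²/Σλ²), orthogonal Procrustes alignment, fingerprinting similarity.
* **Arousal** — behavioral index: per-TR median of the pupil trace divided
  by the scan maximum; arousal template: per-region correlation of BOLD
  with the HRF-convolved behavioral index (Fisher-z averaged over scans);
  fMRI index: spatial correlation of each frame with the template;
  equal-sample rank binning into 10 arousal bins.
* **Dynamics** — two-stage DCC: per-region GARCH(1,1) by QMLE, then scalar
  DCC(1,1) with correlation targeting, giving per-frame conditional
  correlation matrices; bin means, per-bin gradients, gradient-space flow
  with a scan-level arousal-shuffle null, FC entropy, quadratic
  (U / inverted-U) trend classification.
* **Variance partitioning** — `FC = b0 + b1·SC + b2·NS` over region pairs
  (slope ridge, leave-one-scan-out cvR²); single-variable models as upper
  bounds and reduced models (region-identity shuffles of one predictor) as
  lower bounds (ΔR²) on each predictor's unique contribution; frame-wise
  and arousal-binned variants; per-receptor contributions by surrogate map
  replacement.
* **Spatial nulls** — variogram-matched, spatial-autocorrelation-preserving
  surrogate maps (permute → distance-kernel smooth → amplitude/nugget
  rescale), +1-corrected permutation p-values, right-tailed receptor tests,
  Benjamini–Hochberg FDR.
* **Synthetic cohorts** — `dyngrad.synth` generates every input with
  planted truth: orthonormal smooth gradient maps, an AR(1) arousal process
  observed through a noisy blink-interrupted pupil trace, BOLD scans whose
  frame correlation is `w_SC·SC + w_NS(a_t)·NS + rest·I` with a U- or
  inverted-U arousal modulation, a distance-decaying log-normal tracing
  matrix, and receptor expression maps with planted loadings and genuinely
  inert null receptors.

## Worked example

```bash
python examples/04_variance_partition.py
```

prints, for a 40-region cohort with six scans:

```
full model cvR2            = 0.908
SC: single-variable cvR2 = 0.893 (upper bound), deltaR2 = 0.816 (lower bound on unique contribution)
NS: single-variable cvR2 = 0.090 (upper bound), deltaR2 = 0.016 (lower bound on unique contribution)
SC per-bin deltaR2 quadratic coefficient = -0.800 (inverted-U)
NS per-bin deltaR2 quadratic coefficient = +0.485 (U)
```

Reading: the full GLM explains 91% of held-out FC variance; the structural
predictor's unique share dominates statically, and across arousal bins its
unique contribution peaks at mid-arousal (inverted-U) while the
neuromodulatory similarity contributes most at the arousal extremes (U) —
exactly the opposing modulation planted by the generator. The other
examples (`examples/01…05`) cover static gradients, arousal indices,
DCC/dynamic gradients and receptor significance.

A thin CLI wraps the pipeline: `dyngrad simulate` writes a synthetic cohort
as TSV inputs, `dyngrad run --config cfg.toml` (or `--demo`) executes the
enabled stages and writes per-stage TSV/JSON outputs plus a manifest.

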