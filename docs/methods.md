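# Methods

## Model and procedure

The pipeline evaluates two fallback imaging markers for distinguishing
glioblastoma recurrence from post-treatment effect in patients whose DSC
perfusion study is destroyed by susceptibility signal loss:

- **IAUC** (model-free DCE): each voxel's dynamic time–signal-intensity
  curve is low-pass smoothed, normalized to its pre-contrast baseline
  ((SI − SI₀)/SI₀, so the baseline sits at zero), and integrated over the
  first 30 s after contrast arrival. No pharmacokinetic model (Ktrans,
  ve) is fit; the initial area is the marker. The lesion feature is
  **IAUC90**, the 90th percentile of the lesion's cumulative IAUC
  histogram, in units of normalized-SI·seconds (the study never assigns
  physical units; values are treated as arbitrary units).
- **ADC** (DWI): mono-exponential decay between b = 0 and 1000 s/mm²,
  ADC = ln(S₀/S_b)/b, reported in 10⁻³ mm²/s. The lesion feature is
  **ADC10**, the 10th percentile, capturing the densest cellular
  component (high cellularity → restricted diffusion → low ADC).
- **nCBV** (DSC, used only to establish uninterpretability): ΔR2*(t) =
  −ln(S(t)/S₀)/TE; a two-parameter linear leakage correction regresses
  each voxel's curve on the whole-brain mean curve R(t) and its running
  integral (ΔR2*ᵥ ≈ K1·R − K2·∫R), the corrected blood volume is K1·∫R
  over the first-pass window, and the map is divided by its mean over
  contralateral normal-appearing white matter (NAWM). Recirculation is
  eliminated by restricting integration to the contiguous window where
  the reference curve stays above 10% of its peak.

Diagnostics on the 45 analyzable patients (20 recurrence / 25
post-treatment): pooled-variance two-sample t-tests with a Bonferroni
per-test α of 0.025 (two feature comparisons at family level 0.05);
empirical ROC (Mann-Whitney AUC, ties ½) with the Youden-optimal
operating point; leave-one-out cross-validation in which each training
fold re-learns the feature direction and Youden cutoff (univariate) or a
two-feature logistic score (combined), and only held-out predictions are
pooled; and ICC(2,1) — two-way random effects, absolute agreement, single
measure — for inter-reader agreement of each feature.

## Synthetic cohort: what it emulates, and what it does not

No patient-level data exist for this analysis, so a seeded generator
reproduces the *statistical structure* the analysis assumes:

- **Accrual**: 71 patients with uninterpretable DSC (54 hemorrhage, 17
  skull-base); 20 uninterpretable DWI (14 skull-base proximity, 6
  hemorrhage); 12 uninterpretable DCE, all carrying macro-hemorrhage and
  nested inside the DWI-uninterpretable set (a patient whose DWI fails
  from skull-base proximity can still lose DCE to hemorrhage, so the DWI
  artifact cause is recorded separately from the DSC artifact cause);
  3 steroid exclusions and 3 without follow-up among the 51 with both
  modalities interpretable; final 45 split 20/25.
- **Class separation is injected at the feature scale.** Each patient
  draws target (IAUC90, ADC10) values from per-class Gaussians
  (recurrence: IAUC90 8.64 ± 3.96 a.u., ADC10 0.96 ± 0.14; post-treatment:
  5.84 ± 2.63, 0.99 ± 0.19; configurable within-class correlation,
  default 0), and the voxel fields are constructed so the map pipeline
  recovers those targets: lesion enhancement amplitudes are a random
  profile rescaled so its 90th percentile equals the IAUC target, lesion
  ADC a profile whose 10th percentile equals the ADC target. Only the
  group means/SDs are published, so Gaussians are the minimal model.
- **Curve shapes**: DCE enhancement is a gamma-variate wash-in (shape
  α = 1.5, peak 40 s post-onset — the standard bolus form; the source
  analysis specifies only that IAUC is computed from the curve), onset at
  the last baseline sample so exactly 10 baseline dynamics precede
  enhancement. DSC uses a narrower first-pass gamma-variate (α = 3, peak
  6 s after onset) plus a delayed 25%-amplitude recirculation bump, and
  signal-loss regions hold SI at 1% of baseline in every dynamic.
- **Geometry**: 32×32×8 voxel grid per phantom (desk-scale runtime;
  configurable), ellipsoidal lesion (≈210 voxels), box NAWM region,
  2-voxel peritumoral shell of elevated ADC (1.15–1.45·10⁻³ mm²/s,
  vasogenic edema) so mask jitter does not drag ADC10 toward white
  matter, background white-matter ADC 0.78·10⁻³ mm²/s.
- **Noise**: additive Gaussian on SI (DCE baseline 100 a.u., sd 1; DWI
  S₀ 1000 a.u., sd 7; DSC baseline 600 a.u., sd 3). Rician noise is out
  of scope. For DWI, "SNR" is quoted on the diffusion-weighted volume,
  the standard DWI convention, with the same receiver noise sd on both
  volumes.
- **Readers**: two lesion masks per patient, derived from the true mask
  by independently flipping boundary voxels with probability 0.1 — a
  variability model standing in for human segmentation, for which only
  the resulting ICCs were ever published.

**What passing tests do not show about real data**: phantoms are
pre-registered (no motion or co-registration error), anatomy is
geometric, the enhancement of every voxel shares one canonical curve
shape, DWI/DCE interpretability flags are generator-assigned rather than
derived from a neuroradiologist's reading, and reference-standard labels
are inputs, not outcomes of pathology or follow-up. Synthetic-cohort ICCs
(≈0.99 at the default mask jitter) are higher than clinically reported
values because all inter-reader disagreement is boundary jitter; the
pipeline-level claims are therefore structural (ordering, calibration,
invariances), not absolute agreement levels.

## Numerical choices

- **Smoothing**: centered moving average, window 3, edges replicated. At
  this window the filter conserves the curve mean exactly; wider windows
  over-weight replicated edge samples.
- **Arrival detection**: first post-baseline sample exceeding the
  baseline mean + 3·SD for two consecutive dynamics, falling back to the
  first post-baseline sample if no crossing occurs. For maps, arrival is
  estimated once per study from the mean normalized curve over the lesion
  mask: bolus arrival is a global event, and per-voxel thresholding
  detects weakly enhancing voxels systematically late, which at 3.22 s
  per dynamic would inflate their IAUC by ~15% per sample of delay.
- **Integration**: trapezoidal, with the 30 s boundary handled by linear
  interpolation inside the final partial interval (a rectangle-sum option
  exists). The generator calibrates amplitudes against this same
  convention, making generator and pipeline self-consistent; against
  adaptive quadrature of the analytic curve the discrete integral agrees
  within 1%.
- **Nil (signal-loss) voxels**: baseline SI below 5% of the within-brain
  median baseline. Nil voxels carry value 0, are excluded from every
  histogram, and a lesion with ≥25% nil voxels renders the study
  uninterpretable (the qualitative radiological call made reproducible;
  the cutoff is configurable).
- **ADC domain**: voxels with S_b > S₀ (negative ADC) or non-positive
  signal are nil rather than clipped.
- **Percentiles**: linear-interpolation convention (q=0 → min,
  q=100 → max); the nearest-rank alternative differs negligibly at
  ≈200-voxel lesions.
- **LOOCV scoring**: univariate held-out scores are direction·x, which
  pools coherently across folds. Logistic decision scores live on
  fold-specific scales (intercept and coefficients are refit per fold),
  so each held-out score is mapped through its training fold's score
  distribution (ECDF, ties ½) before the pooled AUC is computed; pooling
  raw decision scores deflates cv_auc by ≈0.05 at n = 45. Accuracy uses
  the raw training-fold Youden cutoff (a 0.5-posterior rule is available
  behind a switch). The logistic model keeps scikit-learn's default
  regularization — at n = 45 with one near-noise feature an unpenalized
  fit measurably hurts the combined model.
- **Degenerate inputs**: zero pooled variance in the t-test returns
  t = 0, p = 1 (equal means) or an underflow-safe minimum p (distinct
  means); single-class ROC/LOOCV folds and zero between-subject variance
  in ICC raise errors rather than returning numbers.
- **Seeding**: one integer seed drives a `numpy` generator from which
  per-patient sub-seeds (< 2³¹) are drawn, so cohorts are bit-reproducible
  and any patient can be regenerated in isolation.

## Design decisions that were genuinely open

- The uninterpretability criterion, the arrival rule, the leakage-
  correction form, the percentile convention, the logistic combiner and
  the ICC form are all unstated in the source analysis; the choices above
  are the field-standard ones and each sits behind a parameter or switch.
- Descriptive sensitivity/specificity are resubstitution values at the
  full-sample Youden point and are reported separately from the
  cross-validated quantities, since the source tables are ambiguous about
  which was printed.
- No command-line entry point is installed: the package is an analysis
  pipeline, and the numbered scripts under `analysis/` plus
  `run_pipeline` are its interface.

## Problem sizes

Default phantoms are 32×32×8; the full 71-patient pipeline (maps,
screening, features, diagnostics) runs in a few seconds on one CPU.
Calibration properties are verified over 200 record-level cohorts
(feature targets) plus image-level recovery spot-checks on reduced
20×20×6 grids; the cross-validation surrogates use 200 replicates per
case, at which the Monte-Carlo standard error of the mean cv_auc is
below 0.01.

## Known limitations

- The leakage-corrected nCBV is validated on phantoms whose leakage term
  follows the same two-parameter model the correction assumes; real
  leakage kinetics are nonlinear.
- IAUC amplitude calibration assumes the canonical gamma-variate shape;
  dispersion or delayed enhancement would shift the 30 s area.
- The combined-model cross-validated AUC depends on the score-pooling
  convention (documented above); published values from other software may
  use a different one.
- With two raters ICC(2,1) cannot separate rater bias from interaction;
  agreement statements are limited accordingly.
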