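# gbmalt

Fallback imaging markers for post-treatment glioblastoma when DSC
perfusion MR imaging is uninterpretable.

## The problem

After surgery and chemoradiotherapy, an enlarging contrast-enhancing
lesion in a glioblastoma patient can be tumor recurrence or a
treatment-related change; both enhance because the blood–brain barrier is
disrupted. Dynamic susceptibility contrast (DSC) perfusion — relative
cerebral blood volume normalized to contralateral white matter (nCBV) —
is the usual discriminator, but gradient-echo EPI loses all signal over
intralesional hemorrhage and near the skull base. In those patients the
lesion has a *nil* nCBV value and the DSC study is uninterpretable, so
the question becomes: how well do diffusion-weighted imaging (DWI) and
model-free dynamic contrast-enhanced (DCE) imaging substitute?

This package implements that analysis as a tested, reusable pipeline, with
a seeded synthetic-cohort generator standing in for the clinical data
(which were never deposited):

- **`gbmalt.synthetic`** — digital phantoms: DCE series (gamma-variate
  wash-in over a flat baseline, 120 dynamics at 3.22 s, 10 baseline
  dynamics), DWI pairs (b = 0 / 1000 s/mm², mono-exponential decay), DSC
  series with first-pass bolus, recirculation and signal-loss regions,
  two-reader lesion-mask variability, and whole accrual cohorts
  (71 → 51 → 48 → 45).
- **`gbmalt.maps`** — voxelwise parameter maps. IAUC: smooth the
  time–signal curve, normalize to baseline (baseline set at zero), and
  integrate the first 30 s after contrast arrival. ADC:
  ln(S₀/S_b)/b in 10⁻³ mm²/s. nCBV: ΔR2*(t) = −ln(S/S₀)/TE, two-parameter
  linear leakage correction against the whole-brain reference curve,
  first-pass integration, NAWM normalization.
- **`gbmalt.screen`** — interpretability flagging (nil-fraction of the
  lesion) and the accrual filters.
- **`gbmalt.features`** — lesion cumulative-histogram cutoffs: ADC10
  (10th percentile of ADC) and IAUC90 (90th percentile of IAUC).
- **`gbmalt.diagnostics`** — pooled-variance t-tests (Bonferroni per-test
  α = 0.025), empirical ROC with Youden operating points, leave-one-out
  cross-validated AUC/accuracy of single features and their logistic
  combination, ICC(2,1) inter-reader agreement, and binormal closed forms.
- **`gbmalt.pipeline`** — the end-to-end driver behind the `analysis/`
  scripts.

## Worked example

```python
from gbmalt import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(seed=1234))
print(result.accrual.to_text())
```

```
Accrual cascade
  uninterpretable DSC studies          71
    cause: hemorrhage                  54 (76.1%)
    cause: skull-base proximity        17 (23.9%)
  interpretable DWI                    51 (71.8%)
  interpretable DCE                    59 (83.1%)
  interpretable DWI and DCE            51 (71.8%)
  excluded: steroids at imaging        3
  excluded: no follow-up reference     3
  final analyzable patients            45
```

Every phantom's DSC study is uninterpretable by construction (that is the
cohort's inclusion criterion); the 45 analyzable patients split 20
recurrence / 25 post-treatment. `result.features` holds the two readers'
ADC10/IAUC90 tables and `result.report.to_text()` prints the group
comparisons, ROC operating points, cross-validated performance and
inter-reader ICC. The numbered scripts under `analysis/` run the same
stages one at a time and write their tables under `results/`:

```sh
python analysis/01_simulate_cohort.py    # records + accrual table
python analysis/02_parameter_maps.py     # example ADC/IAUC/nCBV volumes
python analysis/03_screen_accrual.py     # DSC screening + accrual filters
python analysis/04_extract_features.py   # ADC10/IAUC90 per patient/reader
python analysis/05_diagnostics.py        # t-tests, ROC, LOOCV, ICC
python analysis/06_cv_surrogates.py      # Gaussian-surrogate LOOCV AUCs
```

For example, `analysis/06_cv_surrogates.py --seed 1234` prints

```
reader1_iauc90   mean cv_auc 0.727 (±0.005) | binormal 0.722
reader1_adc10    mean cv_auc 0.553 (±0.008) | binormal 0.551
reader2_iauc90   mean cv_auc 0.735 (±0.005) | binormal 0.731
reader2_adc10    mean cv_auc 0.539 (±0.009) | binormal 0.546
```

i.e. the permeability marker IAUC90 carries most of the diagnostic signal
(cross-validated AUC ≈ 0.73), diffusion's ADC10 is close to chance
(≈ 0.55), matching the study the cohort is calibrated to.

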