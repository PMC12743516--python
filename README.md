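# afmvpa

Analysis pipeline for studying accelerometer-derived moderate-to-vigorous
physical activity (MVPA) and major adverse cardiovascular events (MACE) in
atrial fibrillation cohorts, stratified by a comorbidity-based risk
phenotype. Everything runs on synthetic data with known ground truth, so the
full study design is testable without any restricted data access.

## What it does

- **`afmvpa.synthetic`** — generates every input the pipeline needs: clinical
  tables with a latent two-phenotype comorbidity structure (31 binary
  indicators, probit-calibrated continuous variables), log-normal weekly
  MVPA, proportional-hazards event times whose hazard depends on phenotype
  and on a smooth spline function of MVPA, and raw tri-axial accelerometer
  signals with planted activity bouts and non-wear episodes.
- **`afmvpa.accelerometry`** — raw signal to QC'd weekly activity:
  gravity calibration from stationary windows, 5-s epoch ENMO, non-wear
  detection (60-min sliding windows, all-axis SD < 13 mg), intensity
  classification (MVPA strictly above 100 mg) and weekly summaries with a
  3-wear-day QC rule.
- **`afmvpa.phenotyping`** — clinical dichotomization at standard cut-points,
  mode imputation, Ward minimum-variance agglomeration on squared Euclidean
  distances (own implementation with a deterministic lowest-index tie-break),
  cluster cuts and silhouette diagnostics.
- **`afmvpa.survival`** — follow-up construction (6-year cap, index = later
  of diagnosis and accelerometry, or procedure date for the subgroup),
  quartile exposure assignment (remainder to the lowest quartiles),
  Kaplan-Meier curves and a Newton-Raphson Cox solver with Efron tie
  correction (score tolerance 1e-8).
- **`afmvpa.dose_response`** — restricted cubic spline (3 knots at the
  10/50/90 MVPA percentiles) Poisson regression by IRLS with a person-time
  offset, Wald linearity test, delta-method IRR confidence bands, and the
  minimal/optimal dose scan (first significant IRR vs reference; first
  non-significant IRR vs dose − 30 min/week).
- **`afmvpa.pipeline`** — orchestrates QC → clustering → per-cluster quartile
  tables and Cox fits → cluster contrast → pooled dose-response → threshold
  report, with a reconciled exclusion flow log.

## CLI

```sh
afmvpa simulate cohort --n 1000 --seed 1 --out cohort/
afmvpa simulate recording --profile profile.yaml --epoch-mode --out rec.csv
afmvpa accel summarise --in rec.csv --out summary.json
afmvpa phenotype cluster --in cohort/clinical.csv --k 2 --out labels.csv
afmvpa survival fit --records records.csv --exposure quartile --adjusted --out fit.json
afmvpa dose fit --records records.csv --out dosefit.json
afmvpa dose thresholds --fit dosefit.json --step 30
afmvpa run --clinical cohort/clinical.csv --out report/
```

All I/O is plain text (CSV/JSON/YAML). Raw recordings are CSV with a
`# sample_rate_hz=` header line.

## Notable conventions

- Epoch magnitude is ENMO: Euclidean norm minus 1000 mg, floored at zero.
- The sedentary/light boundary defaults to 30 mg (configurable); the MVPA
  threshold is a strict `> 100 mg`.
- Weekly minutes are scaled by `7 / valid_wear_days` (per-valid-day
  averaging available via `scale_to_week=False`).
- Quartile sizes: when `n mod 4 = r`, the `r` lowest quartiles each receive
  one extra individual, so Quartile 1 is never the smallest group.
- 6 years of follow-up = 2191 days.
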