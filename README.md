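# otquant

A validation and quantification pipeline for targeted LC-MS/MS monitoring of
organotin compounds — tributyltin (TBT) and triphenyltin (TPhT) — in bottom
sediments, with deuterated TBT (TBT-d27) as internal standard.

Antifouling-paint residues make TBT one of the most toxic legacy
contaminants in harbour and estuary sediments, and quantifying it there is a
matrix-effect problem as much as a chemistry problem: co-extracted organic
matter, PAHs and fine mineral fractions suppress electrospray ionization
differently in every sediment. `otquant` implements the complete
quantitative workflow a laboratory runs on top of its integrated MRM peak
areas — everything downstream of the chromatogram and upstream of the
monitoring report:

- **Weighted calibration**: y = ax + b by weighted least squares (1/x by
  default), with parameter standard errors, significance, weighted and
  unweighted R², and back-calculation.
- **LLOQ/LOD decisions**: the lowest level with S/N ≥ 5, CV ≤ 20% and
  accuracy 100 ± 20% becomes the LLOQ; LOD = LLOQ · 3 / (S/N at LLOQ).
- **Guideline validation** (EMA-style): accuracy/precision within and
  between runs (85–115% / ≤15% CV, widened to 80–120% / ≤20% at the LLOQ),
  selectivity and carry-over = 100·A_blank/A_LLOQ (<20% analyte, <5% IS),
  stability vs fresh references (85–115%), and a pure-function overall
  verdict.
- **Matrix effects and recovery**: absolute matrix effect
  ME_A = 100·a_matrix/a_water from post-extraction-spike slope ratios;
  relative matrix effect ME_R = CV% of ME_A(analyte)/ME_A(IS) across
  matrices (<15%); extraction recovery RE = 100·A_pre/A_post; paired t-test
  for sieved vs unsieved matrices.
- **CRM trueness**: bias Δ against a certified sediment (BCR 646) tested
  with expanded uncertainty U_Δ = k·√(u_ref² + s_m²/n), compatible ⇔ Δ ≤ U_Δ.
- **Exploration**: Spearman screening of ME_A/RE against sediment
  geochemistry (pH, TOC, AVS, PAH, heavy metals, grain-size fractions),
  standardized PCA with biplot coordinates, Welch tests from summary
  statistics.
- **Censored reporting**: real samples quantified through the IS-ratio
  calibration, averaged, then censored as `below_lod` / `below_lloq`;
  monitoring summaries never impute censored values.
- **Synthetic studies**: a generator with explicit latent truth
  (suppression, recovery, carry-over, noise) that emits every block above,
  so the whole pipeline is testable end to end and estimator bias is
  measurable. See `docs/methods.md` for the model.

The package ships a small example dataset: the ten-sample Odra River
estuary monitoring table (sediment physicochemistry plus the reported
TBT/TPhT concentrations with their "<5 ng/g" censored entries) in
`otquant.datasets`.

## Worked example

Simulate a complete validation campaign, fit every block, and print the
study summary (statsmodels-style: a `ValidationStudy` model whose `fit()`
returns a `StudyResults`):

```python
from otquant import simulate_default_study, ValidationStudy

records, profiles, truth, config = simulate_default_study(seed=1)
results = ValidationStudy(records, config, profiles).fit()
print(results.summary())
```

```
Validation study results
========================

TBT: slope 0.02012 +/- 6.9e-05 (p=3.9e-68), intercept -0.000316, R2(w)=0.9995, one_over_x, is_ratio, n=42
    LLOQ 1 ng/g (S/N 34.5, CV 2.7%, accuracy 104%), LOD 0.087 ng/g
TPhT: slope 0.01212 +/- 5.7e-05 (p=8.3e-63), intercept -0.0008647, R2(w)=0.9991, one_over_x, is_ratio, n=42
    LLOQ 5 ng/g (S/N 101.4, CV 2.8%, accuracy 102%), LOD 0.15 ng/g
ME_A TBT: 59-96% (mean 76.5%, SD 13.0%)
RE TBT: 86-106% (mean 94.9%, SD 6.8%)
ME_A TPhT: 60-99% (mean 75.6%, SD 13.5%)
RE TPhT: 78-101% (mean 92.9%, SD 7.3%)
ME_R TBT: 5.3% over 10 matrices (pass)
ME_R TPhT: 6.5% over 10 matrices (pass)
CRM TBT: measured 450 +/- 19 ng/g (n=6) vs certified 480 ng/g; delta 29.8 <= U_delta 81.5: compatible
CRM TPhT: measured 30 +/- 1 ng/g (n=6) vs certified 29 ng/g; delta 0.9 <= U_delta 11.0: compatible
Samples TBT: 10/10 quantified, max 5151 ng/g, 0 censored
Samples TPhT: 2/10 quantified, max 81 ng/g, 8 censored
Verdict: PASS (accuracy_precision=ok, calibration=ok, carry_over=ok, relative_matrix_effect=ok, selectivity=ok, stability=ok)
```

Reading the output: both calibration slopes are highly significant with
weighted R² > 0.999; the configured LLOQs (1 and 5 ng/g) pass their
S/N/precision/accuracy gates. Ionization suppression varies strongly across
the ten sediment matrices (ME_A down to ~59% in the most PAH-contaminated
one), but the deuterated internal standard tracks it, so the relative
matrix effect stays at 5–7%, far below the 15% limit — the method
quantifies reliably despite the suppression. The measured CRM means sit
within the expanded uncertainty of the certificate (bias 29.8 ng/g against
U_Δ = 81.5 ng/g for TBT), and of the ten real samples all TBT values but
only two TPhT values exceed their quantification limits.

The same pipeline runs from files:

```bash
otquant simulate --seed 17 --out-dir sim/
otquant run --measurements sim/measurements.csv --config sim/config.yaml \
            --sediments sim/sediments.csv
otquant report --measurements sim/measurements.csv --out sim/report.md
```

and individual stages are plain functions (`fit_weighted_line`,
`carry_over`, `trueness_vs_crm`, `relative_matrix_effect`, `spearman`,
`pca`, `quantify`, ...) for use on your own tables.

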