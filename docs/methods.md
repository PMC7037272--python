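# Methods

This note documents the statistical model behind `otquant`, the choices made
where the design was genuinely open, what the synthetic-data generator does
and does not emulate, and the numerical conventions used throughout.

## Scope and measurement model

The package starts at integrated MRM peak areas: chromatogram acquisition and
peak integration are upstream of it, extraction chemistry is outside it. A
study is one long table of peak-area observations, each tagged with its role
in the design (aqueous calibrant, QC replicate, blank, carry-over blank,
pre-/post-extraction matrix spike, stability/reference pair, CRM replicate,
real sample). Concentrations are expressed as ng analyte per g dry sediment
throughout; the conversion from extract concentration to sediment
concentration is a fixed design constant of the wet-lab protocol and never
appears in the statistics.

Two instrument responses are supported and recorded on every fit:

- `raw_area` — the analyte's peak area. Used wherever a ratio of raw
  responses *is* the quantity of interest (matrix effects, recovery,
  carry-over, selectivity).
- `is_ratio` — analyte area divided by the co-measured isotope-labelled
  internal-standard area (TBT-d27). Used for calibration, QC
  back-calculation, stability, CRM trueness and real-sample quantification,
  because the ratio cancels injection-to-injection variability and whatever
  part of ionization suppression the IS shares.

## Weighted calibration

Calibration is the straight line y = a·x + b fitted by weighted least
squares, weights 1/x by default (1/x² and unweighted are available).
Electrospray peak-area noise grows roughly in proportion to signal, so over
a 1–4000 ng/g range unweighted least squares lets the top standards dominate
and wrecks back-calculated accuracy at the bottom; 1/x weighting is the
standard remedy and its benefit is verified as a property (the spread of
back-calculated low-level accuracy is strictly smaller than unweighted over
hundreds of simulated heteroscedastic curves). Parameter standard errors and
two-sided p-values come from the t distribution with n − 2 degrees of
freedom (statsmodels WLS); R² is reported in weighted form, with the
unweighted R² of the same line also emitted for comparison with plain
regression output. Blanks are never calibration points: x = 0 is
incompatible with 1/x weights.

Fitting is deliberately linear-only. The method's validated range is the
linear range; a quadratic or 4PL fallback would mask a failing linearity
check rather than flag it.

## LLOQ and LOD

The lower limit of quantification is decided, not asserted: among the
configured candidate levels (the lowest calibration standards), the LLOQ is
the lowest level whose replicates simultaneously give

- signal-to-noise ≥ 5 (S/N is peak area over the supplied baseline-noise
  estimate; no chromatograms exist at this layer, so the noise figure is an
  input),
- back-calculated CV ≤ 20%, and
- mean back-calculated accuracy within 100 ± 20%.

If no level qualifies, the error names the failing criterion per level. The
limit of detection is then obtained by linear scaling of S/N with
concentration from the LLOQ point: LOD = LLOQ · 3 / (S/N at LLOQ). This
scaling rule is a design decision — the S/N = 3 criterion itself does not
prescribe an arithmetic — and is the simplest rule consistent with a
signal proportional to concentration.

## Guideline acceptance blocks

All acceptance logic follows the EMA bioanalytical-validation conventions
and is a pure function of the computed cells plus the configured thresholds:

- **Accuracy/precision**: accuracy = 100·mean(back-calculated)/nominal,
  precision = 100·sd/mean (sample sd, n − 1). Windows 85–115% and ≤15% CV at
  QC levels, 80–120% and ≤20% at the LLOQ. Within-run cells are computed per
  run (so a min–max range across runs can be reported); between-run cells
  pool all replicates across runs — the pooled CV, not a variance
  decomposition, because single between-run numbers are what validation
  tables report.
- **Selectivity**: mean blank area at the analyte's retention time as % of
  the mean LLOQ-level area; < 20% for analytes, < 5% for the IS.
- **Carry-over**: blank injected after the highest standard, area as % of
  the LLOQ area; same 20%/5% limits. Both ratios are scale-invariant in
  detector units.
- **Stability**: stressed-sample concentration as % of a freshly prepared
  and freshly measured reference (not % of nominal — storing a sample and
  mis-preparing it are different failures); window 85–115%.
- **Relative matrix effect**: see below; < 15%.

The study verdict is the conjunction of the per-block verdicts; blocks
without data are reported as not run rather than failed.

## Matrix effects, recovery, trueness

- **Absolute matrix effect** ME_A = 100 · a_matrix / a_water: the ratio of
  the slope of a five-level post-extraction-spike curve in a sediment
  extract to the slope of the matching aqueous curve. Both curves are fitted
  on raw areas with the same 1/x weighting as calibration (consistency; the
  choice of weighting for these short curves is otherwise arbitrary).
  Values below 100% are ionization suppression, above 100% enhancement. The
  IS is spiked at one fixed amount, so its matrix effect is the area ratio
  at that amount — the slope-ratio definition degenerates for a
  single-level analyte.
- **Relative matrix effect** ME_R = CV% across matrices of
  ME_A(analyte)/ME_A(IS). It is exactly zero when the IS tracks the
  analyte's suppression in every matrix, which is the structural property
  the definition is built to measure.
- **Extraction recovery** RE = 100 · mean(pre-extraction-spike areas) /
  mean(post-extraction-spike areas) at the shared spike level (1000 ng/g).
  Because suppression acts identically on pre- and post-spiked aliquots of
  the same extract, the ratio isolates extraction losses from ionization
  effects. A water-solution reference (optimization-style recovery) is
  supported through the same operation by selecting reference-role records.
- **CRM trueness**: bias Δ = |certified − mean(measured)| is compared with
  the expanded uncertainty U_Δ = k·√(u_ref² + s_m²/n), with s_m the sample
  standard deviation (n − 1; ISO Guide 33 convention), u_ref the certified
  standard uncertainty and k = 2 (≈95% coverage). Compatible ⇔ Δ ≤ U_Δ; the
  boundary counts as compatible. U_Δ ≥ k·u_ref always, so a certificate
  whose k·u_ref already exceeds the bias yields a compatible verdict for
  every s_m ≥ 0 — the acceptance suite checks this bound explicitly.
- **Sieving comparison**: ME_A on matched matrices before/after fine
  sieving is compared with a two-sided *paired* t-test. Pairing is a
  deliberate choice: the same physical sediments are measured twice, and an
  unpaired test would discard that structure. All-zero differences report
  t = 0, p = 1.

## Exploratory statistics

- **Spearman screen**: rank correlation (average ranks for ties; two-sided p
  from the t approximation with n − 2 df, adequate at n ≈ 10) of each
  matrix-effect/recovery response against each sediment property. Missing
  values are dropped pairwise; a pair with fewer than 4 complete
  observations, or zero rank variance, is omitted. No multiple-testing
  correction is applied — the screen is exploratory and reports raw
  p-values so the user can apply one.
- **PCA**: variables are standardized to zero mean and unit variance before
  the singular-value decomposition, because the properties mix units (%,
  mS, mg/kg, µg/kg) and covariance PCA would be dominated by the largest
  numeric scale. Missing values are excluded listwise. Scores, orthonormal
  loadings and % variance are returned for all components; biplot
  coordinates scale the loadings by singular value/√(n−1)
  (correlation-scaled arrows). No figures are rendered — only plottable
  coordinate tables.
- **Welch t from summaries**: group comparisons reported only as
  mean ± sd, n are testable via the Welch statistic computed from the
  summary numbers.

## Censored reporting

Real-sample replicates are averaged *before* censoring (censoring a mean is
not the mean of censored values); results below the LOD are flagged
`below_lod`, between LOD and LLOQ `below_lloq`, and only values ≥ LLOQ are
reported numerically. Monitoring summaries (max, min, counts above
user-supplied cutoffs) are computed over uncensored values, with censored
entries counted separately and never imputed as zero or LOQ/2.

## The synthetic-data generator

The generator emits every block above from an explicit latent truth so the
whole pipeline is testable end to end and estimator bias is measurable.

Expected raw area of analyte a at concentration x in matrix i:

    E[A] = m_ai · r_i^[pre-spike] · (slope_a · x + intercept_a)

with suppression m_ai ∈ (0, 1.3] and recovery r_i ∈ (0, 1.1] (recovery only
for material spiked before extraction). The IS is added at a fixed amount
before extraction, so it carries r_i and its own co-suppression factor.

Observed areas are E[A] · g · (1 + ε) + η, truncated at zero, where g is a
per-injection factor shared by the analyte and IS areas of one injection
(σ = cv_prop·√share, share = 0.85), ε an independent residual
(σ = cv_prop·√(1−share)) and η an additive floor (σ = sd_floor, which also
serves as the baseline-noise estimate behind S/N). Key default choices, all
fixed before use and stated here as the package's own study conditions:

- **Design sizes** mirror the validated method: 7 calibration levels
  spanning 1–4000 (TBT) / 5–4000 ng/g (TPhT) in 6 replicate curves; QCs at
  3/2500/4000 and 15/2500/4000 ng/g plus the LLOQ level, 5 replicates ×
  3 runs; matrix-spike curves at 50/100/500/1000/2500 ng/g over 10
  matrices in triplicate; 6 blanks, 6 carry-over blanks, 6 CRM replicates;
  5 sieving pairs; 10 real samples in triplicate.
- **Noise**: cv_prop = 0.05, sd_floor = 30 area units, with aqueous slopes
  of 1000 (TBT) and 600 (TPhT) area/(ng/g). This puts raw-area CVs near 5%
  (motivating the 1/x weights), IS-ratio CVs near the few-percent level
  validated methods report, and the LLOQ candidates comfortably past their
  S/N ≥ 5 / CV ≤ 20% / accuracy gates. A looser design with S/N ≈ 5 *and*
  CV ≈ 2% at the same level is not realizable under any additive-noise
  model, so the generator favours self-consistency over matching any
  particular printed S/N figure.
- **Suppression** is matrix-driven: a per-matrix base factor drawn from
  U(0.60, 0.95) is shared by TBT, TPhT (lognormal mismatch σ = 0.05) and the
  IS (σ = 0.04). The shared structure is what lets one labelled IS keep
  ME_R at the few-percent level for both analytes; fully independent
  suppression would make the IS useless by construction. One matrix (M01)
  is fixed at m = 0.58 for TBT — the strongest suppression the method
  design must tolerate.
- **Recovery** r_i ~ U(0.85, 1.05) per matrix.
- **Carry-over** is a fixed fraction κ = 2.25×10⁻⁵ of the immediately
  preceding top-standard area, chosen so the expected blank area sits well
  above the additive noise floor (making κ identifiable) while the
  carry-over percentage stays below the 20%-of-LLOQ limit.
- **Blank interference** is 5% of the LLOQ-level expected area (1% for the
  IS), giving selectivity values in the single-digit percent range.
- **Stability** degradation fractions default to +8% (30-day, −25 °C), +5%
  (3× freeze/thaw), −4% (4 h room temperature), +1/+2% (24/48 h
  autosampler): mid-window values emulating a method that passes its
  stability panel, as the validated method did. Boundary behaviour (±14%,
  ±20%) is exercised explicitly through `degrade_for_stability`.
- **Sediment profiles**: contamination-linked properties (PAH, TOC, heavy
  metals, AVS, N, H, P) are monotone increasing transforms of the
  suppression load s = 1 − m (default link s², multiplicative noise 10%),
  the sand fraction decreases with s, and sand+silt+clay sums to 100.
  Ranges bracket estuarine monitoring data (TOC to ~15%, PAH to
  ~74,000 µg/kg, sand 14–51%). With zero property noise the PAH–ME_A rank
  correlation is −1 by construction.
- **Reproducibility**: one global seed; every experiment block draws from
  its own `default_rng([seed, block])` substream, so blocks are
  individually reproducible and insensitive to generation order. Negative
  area draws are truncated at zero rather than resampled; for
  blank-magnitude signals the truth-recovery oracles therefore use the
  truncated-normal expectation, which `expected_truncated_area` provides.

What the generator does **not** emulate: chromatographic peak shapes,
retention-time drift, isotope patterns, inter-day slope drift, non-linear
response at the top of the range, and any correlation between extraction
recovery and sediment properties beyond what suppression induces. Passing
tests therefore demonstrate that the *statistics* are implemented correctly
and identifiable under the stated measurement model — not that the model
captures every failure mode of real sediment extracts.

## Problem sizes

The default simulated study is ≈1,300 measurement records and fits in well
under a second end to end. The test suite's Monte-Carlo batches use 50 full
studies (parameter recovery), 200 curves (weighting benefit), and 100
profile draws (correlation screen power); `scripts/acceptance.py` averages
its pipeline quantities over 10 studies. These sizes keep Monte-Carlo error
comfortably below the tolerances being checked.

## Known limitations

- Between-run precision is the pooled CV; laboratories wanting a
  run-variance decomposition (ANOVA-based intermediate precision) need a
  different estimator.
- The LOD rule assumes S/N linear in concentration down to the LOD; a
  curving baseline would bias it low.
- The Spearman p-value uses the t approximation; for n < 8 an exact
  permutation p would be preferable.
- PCA's listwise missing-data handling discards whole samples; with the
  bundled profiles (four missing PAH entries) a PAH-including PCA keeps
  only six sediments.
- Censored values are reported as flags, not imputed; summaries over
  heavily censored columns are correspondingly coarse.
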