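# Methods

## The score

The continuous metabolic syndrome score (cMetS) summarizes five
cardiometabolic components — waist circumference (WC, cm), mean arterial
pressure (MAP, mmHg), HDL-cholesterol (HDL-C, mg/dL), triglycerides (TG,
mg/dL) and fasting blood glucose (FBG, mg/dL) — in a single continuous
index for children and adolescents aged 7–18 years.  For each component
*x* an ordinary-least-squares regression

    x_i = β0 + β1·age_i + β2·male_i + ε_i

is fitted on the analysis sample and the residual is standardized by the
residual SD (n − p denominator):  z_i = (x_i − x̂_i) / s.  Because HDL-C
is inversely related to metabolic risk its z-score is multiplied by −1.
The score is the sum

    cMetS_i = z_WC + z_MAP + (−z_HDL) + z_TG + z_FBG .

On the fitting sample every z has mean 0 (an OLS identity) and SD
exactly 1 under the n − p convention, so the cMetS mean is 0 by
construction.  Its variance is 5 only when the adjusted components are
uncorrelated; real components cluster, so the variance exceeds 5 (the
test suite checks both directions on correlated and independently
generated cohorts).

The standardization is internal to the analysis sample.  A fitted scorer
applied to a different cohort emits a warning: the score's scale — and
any cutoff derived from it — does not transfer across populations
without revalidation.

### Choices the construction leaves open

* **Adjustment design.**  "Regressing on age and sex" can mean a pooled
  model with a sex indicator, sex-stratified regressions, or a full
  interaction.  The default is the pooled additive model
  (`pooled_age_sex`); `by_sex_age` and `pooled_age_sex_interaction` are
  available and the choice is recorded in run metadata.
* **Age scale.**  Age enters as continuous years even though the
  calibration table groups it in three 4-year bands; continuous age is
  the standard construction for this family of scores.
* **TG transformation.**  None by default.  TG is right-skewed, so an
  opt-in `log_tg` flag standardizes log-TG for sensitivity analysis.
* **Residual SD denominator.**  n − p.  At study scale the difference
  from n is negligible, but the convention is fixed because two of the
  identity checks (z SD = 1, cMetS mean = 0) are stated at machine
  precision.

## The binary MetS label

MetS is defined as at least three of five components under modified
ATP-III pediatric criteria.  Two presets ship because the normative
definition and the summary-table footnotes of the source survey state
different cutoffs, and it is not recorded which produced the printed
tables; neither preset is privileged beyond the default:

| component | `methods_text` (default) | `table_footnote` |
|---|---|---|
| high TG | ≥ 150 mg/dL | > 100 mg/dL |
| low HDL-C | ≤ 40 mg/dL | < 40 mg/dL (boys 15–18 y: < 45) |
| high FBG | ≥ 100 mg/dL | > 100 mg/dL |
| abdominal obesity | WHtR > 0.5 | WC > sex/age 90th percentile |
| elevated BP | SBP or DBP > 90th percentile for sex, age, height | same |

Strict versus inclusive comparators are kept exactly as stated; they
matter at the printed cutoffs (TG = 150 is flagged under one preset and
not the other's threshold logic).

Percentile thresholds resolve **empirically within the cohort** by
default: sex × integer-age bins (bins under 20 subjects merge with the
adjacent age), a within-bin height tertile for blood pressure, and
linear-interpolation (Hyndman–Fan type 7) percentile estimation.  The
height adjustment is named in the definition but no binning is ever
specified; within-bin tertiles are this package's choice.  An external
normative blood-pressure table (CSV keyed by sex, age-year and height
percentile band) can replace the empirical BP reference for fidelity to
published standards, which are deliberately not shipped.  Secondary
flags for the prevalence table use the same machinery: overweight (BMI
between the sex/age 85th and 95th percentiles), obesity (> 95th),
high LDL-C (> 110 mg/dL), high TC (> 200 mg/dL).

Missing-data policy is complete-case per analysis with logged exclusion
counts; the source survey reports no exclusion accounting, so the counts
are surfaced rather than guessed.

## ROC validation

Cutoffs for predicting the binary label from the score use the rule
**positive if score ≥ threshold** (the positivity convention is a
package choice; none is stated in the source).  The curve is evaluated
at every unique score plus a +∞ sentinel; AUC is the Mann–Whitney
probability (concordant pairs + half ties), which the test suite proves
identical to trapezoidal integration.  The optimal cutoff maximizes
sensitivity + specificity, ties broken toward the smallest threshold; a
1e−9 tolerance absorbs floating-point noise in the tie comparison while
staying below 1/(n_pos·n_neg), the smallest genuine difference between
two operating points.

Confidence intervals (95%) are: Wald normal approximation for
sensitivity and specificity (clipped to [0, 1], flagged at the
boundary); the DeLong structural-components variance for AUC (verified
against an independent implementation); and a seeded percentile
bootstrap (default B = 1000, seed 20150101) over the *entire*
cutoff-selection procedure for the cutoff itself, flagged unstable below
10 positives.  The source study reports intervals without naming
methods, so these are declared substitutes recorded in run metadata, not
claims about the original analysis.

Validation is reported for twelve strata: three age bands × (boys,
girls, both), plus boys, girls and both over the full 7–18 range.
Single-class strata yield placeholder rows with a logged warning.

## The synthetic cohort generator

No subject-level data from the source survey are deposited, so the
generator is a first-class module that emulates the cohort the analysis
assumes.  Per subject: sex (52.3% boys, the survey's ratio), age band
(equal thirds by default — band denominators are not published), age
uniform within band, and a latent severity factor L ~ N(0, 1).  Each
component is

    value = stratum_mean + slope·(age − band midpoint) + ℓ·σ·L + noise

where the stratum means/SDs are the published summary-table values
embedded as constants, slopes are the per-sex band-midpoint gradients
(mean of 15–18 minus mean of 7–10, divided by 8 years), ℓ is the
loading as a fraction of the within-age SD (negative for HDL-C), and the
independent-noise SD closes the variance budget so the configured SD is
reproduced exactly.  TG and weight are generated on the log scale
(right-skewed in children) and moment-matched on the natural scale;
for weight this also prevents the positivity floor — only ≈2.4 SD below
the youngest boys' mean — from truncating the lower tail and deflating
the calibrated SD.  Physiologic floors and SBP > DBP + 5 mmHg are
enforced by rejection resampling (redraw, never clip, so no point
masses).  Systolic and diastolic noise share a common component
(correlation 0.85, total SBP–DBP correlation ≈ 0.86) so the pulse
pressure constraint almost never binds and the two BP percentile flags
overlap as they do in survey data.

**Loading calibration.**  The published material gives no covariances,
so the loadings are calibrated, not estimated: the shipped defaults
(weight .40, WC .32, SBP/DBP .22, TG .15, HDL −.18, FBG .10, TC/LDL .12,
height 0) were fixed once so that, under the footnote preset with
empirical percentiles, MetS prevalence lands near the study's reported
5% — measured 7.4% ± 0.15 across seeds at n = 50 000, inside the
configured [3%, 8%] target band — while all component pairs correlate
in the expected directions and abnormality counts increase with L.

**What the generator does not emulate.**  The survey's multistage
cluster sampling, province structure and non-response are out of scope.
Component marginals are Gaussian (or lognormal) with the published
moments; real biochemistry has heavier tails.  One incompatibility is
structural: the published FBG summary (mean ≈ 92, SD ≈ 12–17 mg/dL)
under any thin-tailed marginal puts ~20% of subjects above 100 mg/dL,
whereas the survey reports ~4% high FBG — the printed moments and the
printed prevalence cannot both be matched, and this package matches the
moments (its stated calibration target).  Consequently MetS prevalence
calibrates to the upper half of the target band, and passing tests
demonstrate internal consistency of the method on a plausible joint
distribution, not reproduction of the survey's component prevalences.

## Numerical and reporting conventions

* Heights are cm everywhere; metres appear only inside the BMI formula.
  No rounding inside computations; 2-dp rounding and the p < 0.001
  display floor exist only in the rendered report, never in CSVs.
* Descriptive tests are the textbook ones, delegated to standard
  routines: equal-variance two-sample t, Pearson chi-square without
  continuity correction, one-way ANOVA.  Zero-variance groups return
  NaN with a logged flag rather than an arbitrary statistic.
* The pipeline is a pure function of (config, seeds); re-runs are
  byte-identical, and metadata records every choice the construction
  leaves open (preset, covariate spec, percentile mode, CI methods,
  positivity rule).
* Problem sizes used by the test suite and acceptance script: 50 000
  subjects for the analysis cohort, 300 000 (≈50 000 per stratum) for
  the moment-calibration check, 30 000 (≈5 000 per stratum) for the
  permuted-label null, B = 1000 bootstrap replicates.  These sizes make
  the Monte-Carlo error small relative to every stated tolerance.

## Known limitations

* The score is sample-specific by design; no cutoff shipped or computed
  here applies to any other population.
* Empirical within-cohort percentiles are not normative references: a
  cohort's own 90th percentile flags ~10% by construction, so the
  abdominal-obesity and BP prevalences differ from those obtained with
  external standards.
* The bootstrap cutoff interval at small n (few dozen positives) is
  noisy; its width is only reliably monotone in n at the simulated
  sizes under a fixed seed.
* Binary MetS classification remains the clinically interpretable
  object; the continuous score is a research index.
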