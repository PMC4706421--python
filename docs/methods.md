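# Methods

## The scores

**siMS score.** Each of the five metabolic-syndrome components is divided
by its diagnostic cutoff and the ratios are summed; HDL, the protective
component, enters negatively, and abdominal obesity enters as the
height-normalized waist (2·waist/height, so that the term equals 1 at the
waist-to-height ratio of 0.5 commonly used as the obesity boundary):

    siMS = 2·W/H + Gly/gly_ref + Tg/tg_ref + SBP/sbp_ref − HDL/hdl_ref(sex)

Defaults: gly_ref 5.6 mmol/L, tg_ref 1.7 mmol/L, sbp_ref 130 mmHg,
hdl_ref 1.02 (men) / 1.28 (women) mmol/L. A subject at every cutoff with
W/H = 0.5 scores exactly 3 (1+1+1+1−1), which makes the scale
interpretable without a reference sample — the property that
distinguishes this score from the cohort-fitted alternatives below.
Systolic pressure is used in the composite; mean and average arterial
pressure (MAP = DBP + (SBP−DBP)/3, AvAP = (SBP+DBP)/2) are provided as
derived measures and MAP is the blood-pressure input of the PCA
comparators. A variant flag (`tg_double_ref`) divides the triglyceride
term by 2·tg_ref; it is off by default, the plain form being preferred
for simplicity.

The HDL *score denominators* (1.02/1.28) deliberately differ from the
*classifier thresholds* (1.03/1.29): the score was published with the
former while the harmonized dichotomous definition uses the latter. Both
are separate config fields; the defaults reproduce the published
arithmetic (verified against the published worked examples to ±0.01).

**siMS risk score.** siMS · (age / age_ref(sex)) · f, with age_ref 45
(men) / 50 (women) — the ages at which cardio/cerebro-vascular incidence
conventionally rises, 50 for women reflecting the average menopause age —
and f = 1.2 for a positive family history of cardio/cerebro-vascular
events (≈ 20% excess risk), 1 otherwise. The multiplication always uses
the full-precision siMS value; two-decimal display uses decimal-aware
round-half-up (`display_round`). Family history is three-valued: when
unknown, the risk score is missing unless the caller explicitly opts
into treating unknown as "no event" (`assume_no_family_history`),
because "no event" is a known negative, not a default.

## Dichotomous classification

Adults (≥ 18 y, and adolescents ≥ 16 y) follow the 2009 joint harmonized
definition: waist ≥ 94/80 cm (m/f), Tg ≥ 1.7, HDL < 1.03/1.29 (strict
inequality), SBP ≥ 130 or DBP ≥ 85, glucose ≥ 5.6; drug treatment for a
component fulfils it regardless of the measured value; syndrome = ≥ 3 of
5. Ages 10–<16 use the IDF pediatric shape: obligatory abdominal obesity
(waist ≥ the age/sex 90th percentile) plus ≥ 2 of the other four; below
10 the classification is undefined. The shipped waist-percentile table
is a population-typical placeholder (the consensus definition refers to
population-specific percentiles); users should supply their own via
`PediatricConfig`.

Flags are three-valued. The aggregate status is resolved by interval
logic: ≥ 3 flags known true → present; even with all missing flags true
the count would stay < 3 → absent; otherwise missing. Nothing is imputed,
since this classification is the ROC state variable and imputation would
bias prevalence.

## Comparator scores

**z-sum.** For each component (waist, SBP, Tg, HDL, glycemic variable —
glucose, insulin or HOMA-IR): natural-log transform for Tg, insulin and
HOMA-IR (for distributional symmetry; the base is irrelevant after
standardization); OLS of the component on age and a gender indicator
(female = 0, male = 1, pooled fit with covariate); residuals standardized
to mean 0, sd 1 (ddof = 1); HDL z multiplied by −1; the five z's summed.
OLS is delegated to statsmodels; the test suite cross-checks it against
hand-rolled normal equations to 1e-10. Degenerate designs degrade
explicitly: covariates constant in the sample, or samples too small to
support them (fewer than p+3 cases for p covariates), are dropped with a
warning, down to centering only; a component with (numerically) zero
residual variance raises an error naming the component.

**PCA factor scores.** The five components (MAP as the blood-pressure
input; Tg and insulin/HOMA logged) are standardized and the principal
components of their correlation matrix extracted — correlation, not
covariance, because the components have incommensurate units. "Factor
analysis" here means unrotated PCA with the eigenvalue > 1 retention
rule; no rotation is applied since none is conventionally specified for
these scores. Two score variants: the first-component score, and the
variance-weighted sum (λ₁·PC1 + λ₂·PC2)/(λ₁+λ₂) of the first two
component scores, normalized by total retained explained variance (the
normalization does not affect correlations, the quantity of interest).
When only one eigenvalue exceeds 1 — typical when a single latent factor
drives the components — the weighted sum degrades to the first component
with a warning. Sign convention: each retained component is oriented so
its waist loading is non-negative (triglycerides break a zero-waist tie),
making repeated fits bit-identical. Scikit-learn's SVD-based PCA serves
as an independent oracle in the tests (1e-8).

Both comparators run whole-sample or independently within age strata
(<18, 18–30, 31+). Being fitted quantities, they are exposed as
`ComparatorModel(cohort, spec).fit()` returning a results object with
per-subject scores, coefficients/loadings, explained variance and a
`summary()`.

## Validation statistics

Pearson r with the two-sided p-value from the t distribution (n−2 df),
pairwise complete-case per cell (maximizing n per comparison), optional
natural-log transform of either vector (e.g. for externally supplied
Framingham-type risk columns, which enter only as precomputed values —
the external algorithm itself is out of scope). ROC AUC is the
Mann–Whitney statistic with midrank tie handling,
AUC = U/(n₊·n₋); the 95% CI uses the Hanley–McNeil standard error with a
normal approximation truncated to [0, 1] — the simplest published
estimator, named in the output metadata, since CI methods differ across
statistical packages. Orientation is fixed (higher score ⇒ positive
class); no auto-flipping.

## Synthetic cohort generator

The generator emulates the validation setting: an obesity-enriched
clinical sample of both sexes (34.5% male) spanning ages 7–77, drawn
from a three-group age mixture (weights 0.138/0.305/0.557; means
13.2/24.3/48.2 y; sds 2.8/3.4/10.6) matching published cohort
descriptives for this setting. A scalar latent severity per subject
loads on every component — the single-factor structure repeatedly
reported for the syndrome, and the mechanism that makes cutoff-based,
z-sum and PCA scores mutually correlated. Components are linear in
severity, age (centred at 40) and sex on their modelling scale, with
independent Gaussian noise; Tg and insulin are generated on the log
scale (hence strictly positive); height is an adult draw by sex shrunk
by a linear growth factor below 18; waist derives from a
waist-to-height-ratio draw; weight from a BMI draw; DBP is SBP minus a
positive pulse-pressure draw (guaranteeing SBP > DBP); missingness is
applied last, independently per field, at small per-field rates
(insulin highest at 12%, mimicking the patchiness of insulin assays).
Everything is deterministic given the seed.

Default means/loadings were chosen once as realistic for an obese clinic
population (mean BMI ≈ 31–33 kg/m²) and calibrated so that dichotomous
syndrome prevalence lands near 47% (`scripts/calibrate_generator.py`
prints the calibration report; the test suite asserts prevalence within
±10 percentage points of 46.6% at n = 528). What the generator does
*not* emulate: real covariance detail beyond one factor (no separate
lipid vs. pressure sub-factors), assay error structure, informative
missingness, treated subjects (treatment flags default to false), or
secular/cohort effects. Passing tests therefore demonstrate that the
pipeline recovers the intended structure when the single-factor model
holds — not that any particular clinical cohort will show the same
coefficients.

## Numerical and interface conventions

- Units are fixed (cm, kg, mmHg, mmol/L, mIU/L, years); there is no
  auto-conversion. Implausible magnitudes that indicate mg/dL input
  (glucose > 30, Tg > 40, HDL > 10 mmol/L) raise a unit error, because a
  silent factor-of-18 mistake is the dominant failure mode for
  cutoff-normalized scores.
- Ingestion is lenient about cells (unparseable or invariant-violating
  values become missing, with a warning) and strict about structure
  (missing mandatory columns, duplicate subject ids, unit violations are
  errors).
- Scores are complete-case per subject and per score; missingness is
  monotone (removing an input can only remove results).
- Score tables serialize at 8 significant digits, so the CSV round-trip
  is exact well beyond the 6-figure display precision; missing values
  are empty cells.
- CLI exit codes: 0 success, 2 schema/configuration error,
  3 computation error. The reference configuration in force is logged
  for auditability.

## Known limitations

- The score is cross-sectional severity, not a calibrated absolute event
  probability; no outcome follow-up is modelled, so no risk cutoff is
  provided.
- The pediatric waist percentiles shipped as defaults are placeholders;
  population-specific tables should be supplied for real use.
- The Hanley–McNeil CI is approximate (no DeLong covariance estimator).
- Treated-but-controlled subjects affect only the dichotomous
  classification (treatment flags), not the continuous scores, which use
  measured values only.
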