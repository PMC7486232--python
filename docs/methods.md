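# Methods

`depval` implements the complete workflow for externally validating a
transferable adolescent depression risk score between two culturally distinct
cohorts: a low-prevalence development population and a high-prevalence
validation population that includes former child soldiers. Because no
individual-level data from either cohort are publicly deposited, the package
ships a synthetic-data generator that reproduces the statistical structure the
analysis assumes, and every downstream stage is exercised against it.

## The risk model

The score is a penalized maximum-likelihood (PMLE) logistic regression over
seven binary predictors (biological sex, caste/ethnicity, drug use, school
failure, social isolation, fight involvement, childhood maltreatment):

    maximize  l(alpha, beta) - (lambda / 2) * sum_j (s_j beta_j)^2

with `l` the Bernoulli log-likelihood, the intercept `alpha` unpenalized, and
`s_j` the standard deviation of predictor `j` in the fitting data, so the
ridge penalty acts on standardized coefficients. Fitting is by Newton
iteration with step-halving (gradient-norm tolerance 1e-8, at most 100
iterations); the penalized objective is strictly concave for `lambda > 0`, so
coefficients stay finite even under quasi-separation. Standardization
constants are stored in the serialized model so that transfer and refits are
reproducible.

Penalty strength is selected on a non-negative grid by a modified AIC:
`LR - 2 * df_eff`, where `LR` is the likelihood-ratio chi-square against the
intercept-only model (unpenalized log-likelihoods) and the effective degrees
of freedom are `trace(I (I + P)^-1)` with `I` the observed information at the
penalized solution and `P` the penalty Hessian. Ties break toward the larger
penalty. A lasso-type penalty is out of scope: the quadratic form is the
conventional reading of PMLE in the clinical-prediction literature this
workflow follows.

Zero-variance predictors are a real feature of the problem — in the
validation population nobody reports drug use — and are handled explicitly:
unidentifiable at `lambda = 0` (an error), forced to coefficient 0 with a
warning under a positive penalty, and always retained in the schema so a
transferred development coefficient simply contributes nothing.

## Outcome and eligibility

The outcome is clinically relevant depression measured by an 18-item
self-rating scale scored 0/1/2 per item (total 0–36); a total of **14 or
above** classifies as depressed. The analysis sample keeps subjects who were
under 18 at waves 1–2, 18 or older at wave 3, assessed at every wave, and
sub-threshold at waves 1–2. Age exactly 18 at wave 1 or 2 excludes — the
inclusion phrasing ("younger than 18") is taken at face value, since the
source criteria are ambiguous about that boundary; the audit trail records
every applicable exclusion reason per subject, and there is no imputation.

## The validation ladder

1. **Standard** external validation applies the development model unchanged.
   When the target prevalence exceeds the development prevalence the model
   under-predicts, which appears as a large positive calibration-in-the-large.
2. **Adjusted** validation re-estimates only the intercept by maximum
   likelihood with the transferred linear predictor as a fixed offset (slope
   pinned at 1). The offset-model score equation matches mean predicted risk
   to observed prevalence exactly, so the adjusted calibration-in-the-large
   is 0 by construction; because an intercept shift is strictly monotone, the
   AUC is exactly unchanged. This is the standard recalibration-in-the-large
   update, not a heuristic mean-matching on the probability scale.
3. **Refitted** validation re-estimates all coefficients in the target cohort
   with the same PMLE machinery (grid-selected penalty by default;
   unpenalized refit available, for which the ML score equations force
   apparent slope 1 and calibration-in-the-large 0 — used as invariant
   checks). A penalized refit compresses predicted log-odds, so its apparent
   calibration slope sits at or above 1.

## Metrics

- **AUC / c-statistic**: pairwise concordance with ties counted one half,
  computed by the rank-sum identity; confidence intervals by seeded
  nonparametric subject resampling (percentile, B = 2000 default; resamples
  with a single outcome class are redrawn). The bootstrap flavour is
  percentile because nothing constrains it further; the asymmetric printed
  intervals this field reports are consistent with that choice.
- **Brier score**: mean of `(p_i - y_i)^2`.
- **Calibration-in-the-large**: the intercept of the one-parameter offset
  recalibration, solved exactly by bracketed root finding on its score
  equation. It is reported on the log-odds scale — values like 2.2 exceed any
  possible probability difference, which fixes the scale convention.
- **Calibration slope**: the slope of the free two-parameter logistic
  recalibration of the outcome on predicted log-odds (statsmodels GLM).
- **Unreliability test**: the likelihood-ratio statistic comparing the free
  recalibration against the fixed null (intercept 0, slope 1), referred to a
  chi-square on **2 degrees of freedom** (joint intercept-and-slope null; the
  2-df reference reproduces printed p-values such as 0.874 at statistic
  0.2702, which a 1-df reference would not).
- **Flexible calibration curve**: tricube locally weighted local-linear
  regression (span 0.75 default) on an even grid over the observed prediction
  range, with pointwise normal-approximation bands from the local binomial
  variance. Samples under 20 are refused (grouped calibration is the honest
  display there); constant predictions yield a flagged degenerate curve.
- Probabilities are clamped to `[1e-12, 1 - 1e-12]` before any logit.

## Sensitivity analyses

- **Interaction**: an unpenalized logistic fit of the outcome on the
  transferred linear predictor, the group flag (former child soldier), and
  their product, with a Wald test on the product term.
- **Categorical NRI** for adding soldier status to the score. The extended
  model keeps the transferred linear predictor as an offset and adds a free
  intercept and soldier coefficient — the minimal "score plus new predictor"
  extension; the source analysis does not specify the form. Risk categories
  are two-level with the boundary assigned high; the cut-point defaults to
  the observed outcome prevalence (a prevalence-anchored choice; the original
  cut-point is unstated) and is configurable. Components follow the standard
  convention in which improvement is positive for events **and** non-events;
  since some reports print the non-events component with the opposite sign, a
  clearly labeled paper-convention rendering (`NRI- = -nri_nonevent`) is
  included. The asymptotic SE combines the components' binomial variances;
  the CI is a seeded percentile bootstrap (B = 2000).

## The synthetic-data generator

Each cohort is drawn as: independent Bernoulli predictors at configured
marginal frequencies; a Bernoulli group flag; a logistic outcome whose
intercept is solved **exactly** (enumeration over predictor patterns plus
Brent root finding, supported up to 20 active predictors) so the population
prevalence hits its target; and symptom totals drawn from truncated discrete
(geometric-tail) distributions on either side of the clinical cutoff, so that
scoring the totals reproduces the generated outcome exactly. `dsrs_noise` is
the mean distance of case totals above the cutoff (default 3 points;
non-case totals sit below it with roughly twice that spread), which keeps
nearly all mass below ~22, the upper range typically seen in community
adolescent samples. Ages are uniform integers on a configured wave-1 range
with wave spacing 1 and 4 years; attrition is monotone missing-at-random per
wave; an optional fraction of subjects carries an above-cutoff record at
wave 1 or 2 to exercise the prior-depression exclusion.

Default conditions mirror the study populations: validation-like cohorts use
the printed marginals (female 34.1%, low caste 18.3%, maltreatment 47.7%,
school failure 14.3%, social isolation 5.6%, drug use 0%, fights 13.5%,
soldiers 43.7%), target prevalence 19.8%, 516 subjects at baseline with
11.6%/43.8% follow-up loss; development-like cohorts use prevalence 3.1% and
drug use 62.4%. Two quantities the source material does not print were fixed
once: the development cohort's remaining marginals (set equal to the
validation values, as the only printed anchors) and the data-generating
log-odds effects (modest values between 0.4 and 0.9, typical of binary
psychosocial risk factors). The group flag's outcome effect defaults to 0,
so the interaction null holds by construction.

What the generator does **not** emulate: predictor correlation (only
marginals are anchored; independence is the default, with correlation left
as a config extension), informative dropout, measurement error in
harmonized predictors, and item-level symptom structure. Passing tests
therefore demonstrate correctness of the estimators and transfer machinery
under a clean data-generating process, not robustness to those real-data
complications.

## Problem sizes and numerical choices

The bundled analysis uses a development cohort of 4,000 (about the size of a
large birth-cohort analysis sample) and a validation cohort of 516 at
baseline, filtering to an analysis sample near the study's 126; simulation
suites use 100 replicates at n = 5,000 for coefficient recovery, 400 null
replicates for the two type-I-error checks, and 200 replicates at n = 126
for bootstrap-interval coverage — sizes at which the binomial Monte-Carlo
error of each check is comfortably inside its assertion band. Rendered
tables round half-even to 2 decimals while JSON artifacts keep full
precision; every random draw flows from explicit seeds, and rerunning any
pipeline with the same config reproduces its numeric outputs byte-for-byte.

## Known limitations

- The published headline numbers (AUC 0.73/0.83, Brier 0.18/0.14/0.12,
  calibration-in-the-large 2.24, slopes 1.18/1.50, NRI 0.0205) depend on the
  unavailable real cohorts; synthetic runs reproduce their qualitative
  pattern and scale, not those exact values.
- The original development model's penalty magnitude and coefficients are
  not published; transfers here use models developed on synthetic data.
- Eligibility at the age-18 boundary and the NRI cut-point follow the
  explicit conventions above; both are configurable where the source is
  silent.
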