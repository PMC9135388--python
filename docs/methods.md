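# Methods

## The analysis model

The pipeline treats a cross-sectional survey of autistic (case) and
non-autistic (control) adults as a case-control comparison of
self-reported healthcare quality.  Three estimands recur:

* **Per-item association.** For each survey item, the 2×2 table of
  endorsement by group (missing responses excluded) yields the
  cross-product odds ratio OR = (a·d)/(b·c) with the Wald interval
  exp(ln OR ± z₀.₉₇₅·√(1/a + 1/b + 1/c + 1/d)), paired with the
  two-sided Fisher exact p-value.  The conditional maximum-likelihood OR
  (maximizer of the noncentral hypergeometric likelihood, as exact-test
  routines report) is available as an alternative; the two differ only in
  the third decimal at this study's sample sizes.  Any zero cell triggers
  the Haldane–Anscombe 0.5 correction, flagged on the estimate.
* **Covariate-adjusted association.** Binomial logistic regression of the
  outcome on the exposure plus age (continuous, years), ethnicity
  (binary), education (5 categories), and country (7 categories).  Age
  enters continuously even though the descriptive tables bin it; the
  categorical covariates use first-level reference coding with levels
  taken from the observed data.
* **Score-based classification.** A single-predictor logistic model of
  autism status on one inequality score, trained on a stratified 20%
  split and evaluated on the remaining 80% at a 0.5 probability
  threshold.  Training on the minority split is unusual but is the
  published procedure and is kept; a `repeats` option averages over
  seeded re-splits since a single split is noisy.

Significance uses a fixed p < 0.001 threshold with additional stars at
p < 10⁻⁴ and p < 10⁻⁵ (half-open intervals), and no FDR correction —
the study's own multiple-comparison stance.  P-values below double
precision (2.22 × 10⁻¹⁶) are displayed as a bound, matching the source
convention.

## Inequality scores

Likert responses collapse to endorse (either Agree) or reject (either
Disagree).  Each item carries a polarity flag: the negative experience is
agreement for problem statements and disagreement for ability statements.
A respondent's section score is (negative-experience points) / (answered
items); the total score pools the 31 items of the five scored sections
(sensory 7, communication 5, anxiety 6, access-advocacy 8,
system-problems 5).  Scores are undefined (and excluded from models) when
no item of the section was answered.  Score models run on two scales:
`proportion` (OR per full 0→1 sweep of the score; large magnitudes) and
`points` (OR per additional negative item).  When everyone answers all
31 items the two are linked exactly by OR_points = OR_proportion^(1/31),
which the tests assert; with item nonresponse the relation is only
approximate, which is why both scales are carried rather than one being
derived from the other.

## Multiple imputation

Ethnicity, education, and country may be missing (≈5.3%, 1.1%, 1.9% under
the default study conditions); outcomes and exposures are never imputed.
Because the incomplete variables are categorical, imputation is by
chained multinomial sampling: each variable is modelled by multinomial
logistic regression on age, the case indicator, and the other covariates'
current completed values, and missing cells are drawn from the predicted
class probabilities.  Three update cycles per table are used — with
missingness this light and completely at random, the chained draws are
already stationary after the first cycle or two — and m = 5 completed
tables are produced.  Estimates are pooled by Rubin's rules
(T = W + (1 + 1/m)·B) with the Barnard–Rubin degrees of freedom for the
t reference; when between-imputation variance is zero the pooled fit
reduces exactly to the complete-case fit.  Imputation refuses to run when
any covariate exceeds 50% missingness.

Perfect separation in any per-table fit (a covariate level that
deterministically predicts the outcome) is detected through diverging
Wald standard errors (> 10 on the log-odds scale) or non-convergence; the
whole pooled estimate is then withheld and flagged rather than reported.

## The synthetic cohort generator

Respondent-level data from such surveys are not shareable, so the
generator is first-class, tested code that plants known truth for every
downstream stage.  Its defaults are the study conditions: 1285 cases and
1364 controls in the analysis cohort plus 1371 incomplete, 112 duplicate,
and 26 unconfirmed-status records (4158 records in all; the incomplete
bucket also stands for the survey's consent/age failures, which the
published flow does not separate).  Item endorsement uses the published
control rates as p₀ and inverts the OR definition for cases:
p₁ = OR·p₀ / (1 − p₀ + OR·p₀).  Covariate marginals follow the published
demographics; age is truncated normal on [16, 96] rounded to years; the
trait score (AQ-10, an integer 0–10 screening score) is clipped rounded
normal per group; "Other" assigned sex occurs only in the case group, as
in the study.  Condition flags use the published sex-specific ORs, but
the published tables give no control base rates, so plausible lifetime
prevalences are assumed (anxiety 0.25/0.20 for F/M, depression 0.30/0.25,
arthritis 0.12/0.08, breathing 0.12/0.10, insomnia 0.12/0.10,
ADHD 0.04/0.05).  Covariate missingness is MCAR (no mechanism is
published); item nonresponse is 5% per question, inside the reported
<10%.  Appointment dates are uniform over 2019-07-01..2021-01-31 with 15%
partial and 5% absent, exercising the full-date filter.

Planted duplicates are appended copies of complete confirmed records
(fresh pid), so arrival order makes the original the kept record.
Accidental 12-criteria collisions among distinct synthetic respondents
(expected by chance at study scale) are resolved by redrawing age, so the
planted manifest is the exact ground truth for duplicate detection —
on real data the detector may of course flag coincidental matches.
Incomplete records carry no answer in any of the eight
completeness-defining sections; unconfirmed records either report a
diagnosis without its confirmation fields or a self-identified label
(suspected / awaiting assessment / self-diagnosed).

### Item dependence and the calibrated configuration

By default items are conditionally independent given group — the
dependence structure of the real items is not published, and
independence is the neutral choice for effect-recovery testing.  Its
known cost: the 31-item total score concentrates sharply around each
group's mean, separating the groups far more cleanly than the real data
do.  Two optional respondent-level random intercepts (logit scale)
induce realistic within-respondent correlation:

* `latent_trait_sd` — a negative-experience propensity, entering with the
  item's polarity sign;
* `response_style_sd` — acquiescence, raising agreement with every Likert
  statement regardless of polarity (checkbox sections exempt).

`score_calibrated_config()` sets `response_style_sd = 4.5`, sized so that
total-score classification accuracy on the synthetic cohort matches the
published ≈72% — the one published measure of score overlap.  In that
regime the published qualitative pattern (high sensitivity, much poorer
specificity for the total score) emerges and is asserted as an ordering
only.  The published metric triple itself (72.000 / 93.778 / 25.882)
cannot be reproduced by any consistent confusion matrix: it violates the
identity accuracy = prev·sens + (1 − prev)·spec, which this package's
metrics satisfy exactly.

What passing tests on synthetic cohorts establish: the pipeline recovers
planted marginal and conditional effects, its ledger bookkeeping is
exact, and its estimators agree with independent oracles.  What they do
not establish: anything about the real cohort's adjusted estimates,
score-model ORs, trait-score means, or classification metrics, all of
which depend on the unreleased respondent-level data.

## Numerical and design choices

* Duplicate match keys compare all 12 criteria fieldwise with
  missing == missing; an anonymized exact-match algorithm cannot
  distinguish two absent values.
* Exclusion order is fixed (consent/age → incomplete → duplicate →
  unconfirmed), each pid appears under exactly one reason, and
  input = output + exclusions is asserted on every run.
* "Unconfirmed age" is operationalized as missing/non-numeric age; under-16
  respondents are excluded with it.
* Era assignment: the cutoff day (2020-03-11) itself is "during"; partial
  dates are excluded, ISO and day-first slash dialects are parsed, and
  two-digit years are rejected rather than guessed.  Within-group era
  contrasts report odds(during)/odds(pre).
* The decision threshold for classification is 0.5 on predicted
  probability (none is published; groups are near-balanced).  On
  perfectly separated training scores the logistic MLE diverges and a
  midpoint-threshold rule (equivalent boundary, flagged) is used.
* Problem sizes in the test-suite simulations (e.g. 2000/group × 50
  replicates for adjusted-OR coverage, 5000/group for marginal
  convergence) were chosen to give the binomial checks comfortable power
  at their stated tolerances.

## Known limitations

* Conditional independence given group (the default) understates
  real-world score dispersion; the calibrated configuration restores
  realistic overlap for classification but attenuates the planted
  marginal item ORs, so effect-recovery tests use the default.
* The chained-equation imputer conditions on a fixed predictor set (age,
  case status, other covariates); it does not model interactions.
* MCAR missingness everywhere; no MAR/MNAR mechanisms.
* No ordinal modelling of the 4-level Likert responses (the analysis is
  defined on the binarized form) and no modelling of free-text answers.
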