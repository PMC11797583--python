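# Methods

## Scoring tables

The three scales are additive eight-item questionnaires with a shared
0–26 range. Age, BMI and the five fixed items (activity 0/2, fruit and
vegetables 0/1, antihypertensive medication 0/2, history of high glucose
0/5, family history 0/3/5) are identical across scales; only the
waist-circumference item differs:

| scale | men | women |
|---|---|---|
| FINDRISC | < 94 cm: 0, 94–102: 3, > 102: 4 | < 80: 0, 80–88: 3, > 88: 4 |
| LA-FINDRISC | < 94: 0, ≥ 94: 4 | < 90: 0, ≥ 90: 4 |
| CUBDRISC | < 90: 0, ≥ 90: 4 | < 80: 0, ≥ 80: 4 |

Band closure follows the tables' wording: middle bands are closed on both
ends (BMI 25–30 → 1 point includes both 25.0 and 30.0; waist 94–102 → 3
points includes 102.0), outer bands are strictly open at the shared
boundary. Age bands are integer-year bands < 45 / 45–54 / 55–64 / ≥ 65.
Risk categories follow the printed band table (≤ 6 low, 7–11 slightly
elevated, 12–14 moderate, 15–20 high, ≥ 21 very high); where a narrative
variant of the high band (15–19) circulates, the printed table is treated
as operative. A spouse's gestational diabetes counts as second-degree
family history (3 points). An explicit BMI takes precedence over one
derived from height and weight (weight/height², unrounded). Missing items
raise an error naming the item; nothing is imputed.

Scale definitions serialize to JSON with explicit per-band inclusivity
flags, because the mixed closure above cannot be expressed by bare
`[lower, upper]` pairs under a single open/closed convention.

## OGTT classification

Canonical unit mmol/L; mg/dL divides by 18.0 (the common clinical
convention; the 0.09% difference from the exact molar factor is far below
threshold resolution). Decision order: DM2 if fasting ≥ 7.0 **or** 2-h
≥ 11.1; else the AFG (fasting ∈ [5.6, 7.0)) and AGT (2-h ∈ [7.8, 11.1))
flags combine into AFG+AGT / AFG / AGT; else normal. Values exactly on a
threshold belong to the higher category, since every defining inequality
at a lower bound is "≥". The five states partition the plane of valid
pairs — verified exhaustively on a 10⁶-point grid that includes the exact
threshold values. Thresholds are overridable via a JSON-serializable
config.

## Accuracy statistics

- Test-positivity convention: score ≥ cutoff.
- Se, Sp, PPV, NPV carry Wilson score intervals; a metric with a zero
  denominator is reported as undefined rather than NaN.
- LR⁺ and LR⁻ use the log-transform interval
  SE(ln LR⁺) = √(1/tp − 1/(tp+fn) + 1/fp − 1/(fp+tn)); a zero cell makes
  the ratio 0 or ∞ with a one-sided, continuity-corrected bound.
- The ROC curve takes one point per distinct observed score plus a +∞
  sentinel. The trapezoidal area over this step curve is algebraically
  identical to the pairwise-comparison statistic
  P(case > control) + ½ P(tie); the suite asserts agreement to 1e-12.
  The AUC interval uses the Hanley–McNeil standard error, and the point
  estimate is graded excellent / very good / good / sufficient / poor /
  not useful at 0.9/0.8/0.7/0.6/0.5 (left-closed).
- Optimal cutoffs maximise Youden's J over all integer cutoffs in the
  observed range; the LR-constrained variant first restricts to cutoffs
  with LR⁺ > 2 and LR⁻ < 0.5 and falls back to plain Youden (flagged) when
  none qualifies. Ties break toward the lower cutoff, favouring
  sensitivity in screening. All-identical scores are rejected.
- Exact CI methods are a package choice (the source analyses used
  closed-source software without documenting theirs): Wilson, log-method
  and Hanley–McNeil are standard, closed-form and reproducible, so
  published intervals are matched approximately, not bit-exactly.
  Published PPV/NPV panels of this study design are not algebraically
  consistent with their own Se/Sp and group totals; PPV/NPV here are
  always computed from the 2×2 table.

## Concordance

Cohen's κ on the 2×2 agreement table of two dichotomised scales. The
reported standard error is the Fleiss–Cohen–Everitt large-sample SE; the
p-value uses the asymptotic SE under H₀: κ = 0 with a two-sided normal
reference (the pairing most statistical packages print). Strength is
banded per Landis–Koch after rounding half-up to two decimals, with any
non-positive κ graded "poor" — so a positive κ below 0.005 still grades
"slight" rather than falling into an unaddressed gap between 0 and 0.01.
Both-raters-constant input (pₑ = 1) raises an explicit undefined-kappa
error.

## Synthetic cohort generator

The generator emulates a risk-factor-enriched adult screening population.
Defaults are the published marginals of that population: 58.7% women; age
bands 34.7/19.9/19.3/26.1% (< 45 / 45–54 / 55–64 / ≥ 65); BMI bands
46.5/35.9/17.6% (< 25 / 25–30 / > 30); physical activity 53.3%; daily
fruit/vegetables 17.4%; antihypertensive treatment 47.5%; prior high
glucose 35.5%; first-degree family history 29.9%; outcome mix
65.5/21.4/3.5/3.2/6.4% (normal/AFG/AGT/AFG+AGT/DM2), i.e. 34.5%
dysglycemia. Second-degree-only family history is unreported in the
source tables; the default is 0.15, configurable.

Sampling: ages uniform integers within the drawn band; BMI from a
log-normal (μ = log 26, σ = 0.16) truncated to the drawn band; waist
circumference log-normal around base(sex) + 1.15·BMI (base 62 cm men,
55 cm women, σ = 0.07 on the log scale), giving abdominal-obesity rates
near the published 75.7% (women ≥ 80 cm) and 56.3% (men ≥ 90 cm). Items
are otherwise independent — the published record provides marginals only,
and this is the simplest joint structure that reproduces the analysis's
qualitative behaviour (AUC ≈ 0.75, near-perfect inter-scale kappa).

The glycemic state follows a proportional-odds link on the FINDRISC
total, P(state ≤ k | s) = σ(c_k − β·s), with the four intercepts solved
by root-finding on the realised score distribution so the marginal state
frequencies match their targets up to Monte-Carlo noise. The default
slope β = 0.22 per point was fixed once by a calibration experiment
(slopes 0.15–0.30 at n = 20 000) as the value placing the dysglycemia AUC
near 0.75; β = 0 gives AUC 0.5 and AUC increases strictly with β. The
glucose pair is then drawn from per-state truncated normals confined to
the state's diagnostic box (uppers shrunk by 0.006 mmol/L so 2-dp
rounding cannot cross a threshold), which makes the
classify-the-generated-pair round trip exact for every record.

An opt-in `require_risk_factor` post-filter rejection-samples until every
record carries at least one eligibility criterion (age ≥ 45, BMI ≥ 25,
family history, abdominal waist, antihypertensive treatment, sedentary
lifestyle, plus extended clinical criteria when supplied). It is off by
default: the filter removes the ~1.5% of draws that are systematically
low-risk, which would bias the configured marginals (the defaults already
describe the enriched population).

What passing tests do **not** show about real data: the generator cannot
reproduce the unpublished joint distribution of items, so published
kappas, AUCs and sex-stratified cutoffs are not recoverable targets —
those quantities are covered instead by internal-consistency and
property-based checks (AUC–pairwise identity, kappa worked examples and
band edges, partition exhaustiveness, marginal recovery within three
binomial standard errors at n = 100 000, Youden-cutoff recovery within ±1
of the link-implied optimum at n = 50 000, all at fixed seeds).

## Pipeline and reports

Reports are TSV (UTF-8, Unix newlines) with percentages at one decimal,
LR⁺ at one decimal, LR⁻ at two and κ/AUC at three — the precision of the
published tables. Records lacking a complete OGTT are scored but excluded
from evaluation and counted in the run log (seed, config hash, record and
exclusion counts). Identical config and seed produce byte-identical
outputs. Group-by stratification (e.g. sex) reruns the identical accuracy
and optimal-cutoff machinery per stratum.

Problem sizes used by the automated checks — 10⁶ grid points for the
partition property, 100 000 records for marginal recovery, 50 000 for
cutoff recovery, 3 000-record cohorts for evaluation fixtures — keep the
whole suite in the seconds-to-minutes range on a single CPU.

## Known limitations

- Percentage risk labels (1/4/17/33/50%) are reported labels, not a
  longitudinal model; no incidence modelling is attempted.
- No HbA1c pathway, repeat-test confirmation, missing-item imputation or
  weighted/multi-rater kappa.
- Paired AUC comparison tests (DeLong), decision-curve analysis and
  calibration metrics are out of scope.
- The synthetic generator's independence assumptions understate real
  covariate correlation (e.g. age–activity, BMI–hypertension); absolute
  synthetic kappas/AUCs are illustrative, not estimates of any real
  population's values.
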