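# Methods

This note records the statistical procedures metscreen implements, the
defaults it ships, and the design choices made where the underlying
analysis left the details open.

## Indices

BMI = w/h², TMI = w/h³, fat mass = BF%/100 × w, FMI = fat mass/h³, with
weight w in kg and height h in metres.  Heights supplied in centimetres
are detected by a plausibility threshold (values > 3 are treated as cm)
and converted on read.  TMI ≡ BMI/h holds to machine precision and is
property-tested.  FMI uses BF% × weight rather than a device-reported fat
mass; the two can differ slightly on bioimpedance instruments that round
internally.

Mean arterial pressure defaults to the physiological estimate
MAP = DBP + (SBP − DBP)/3.  The arithmetic mean (SBP + DBP)/2 is available
behind a flag because published adult descriptives in this literature are
often consistent with that convention while paediatric ones follow the
standard formula; both are exposed so either table style can be
reproduced.

The LMS z-score is z = ((x/M)^L − 1)/(L·S) for L ≠ 0 and ln(x/M)/S at
L = 0 (the L → 0 limit; tested for continuity at |L| < 1e−12).  L, M and S
are linearly interpolated between tabulated ages within sex; ages outside
the table raise an error rather than extrapolate.  No growth-reference
table is bundled — references such as the WHO 2007 tables are distributed
by their publishers and are supplied by the user as delimited text
(`sex,age,L,M,S`).  Test fixtures use small synthetic LMS tables.

## MetS classification

Adult criteria (harmonized IDF thresholds): waist ≥ 80 cm (women) / 90 cm
(men); triglycerides ≥ 150 mg/dL; HDL-C < 50 (women) / 40 (men) mg/dL;
SBP ≥ 130 or DBP ≥ 85 mmHg; fasting glucose ≥ 100 mg/dL.  All comparisons
are inclusive/exclusive exactly as written.  MetS is called at ≥ 3 of 5
abnormal components; the count threshold and an optional mandatory
component (canonical IDF treats central obesity as obligatory) are
configurable, with the uniform ≥ 3 rule as the default.

Paediatric criteria (de Ferranti-style): triglycerides ≥ 100 mg/dL;
HDL-C < 50 mg/dL (< 45 for boys aged ≥ 15); waist above the sex-specific
75th percentile; SBP *or* DBP above the age/sex 90th percentile (the
source definitions are ambiguous on which pressure; we flag on either);
glucose ≥ 110 mg/dL.  Percentile lookups are user-supplied tables keyed by
sex and whole-year age (nearest tabulated age is used).  For self-contained
runs — and for synthetic cohorts, which have no external reference
population — `PediatricPercentileTables.from_cohort` derives the
percentiles empirically from the analyzed cohort itself.  Empirical
percentiles make the waist flag hit ~25% of each sex/age cell by
construction, which is the intended behaviour of percentile-based
definitions but means paediatric prevalence partially reflects the
cohort's own distribution.

Continuous MetS score: each of waist, MAP, triglycerides, HDL and glucose
is z-scored over the whole analyzed cohort (sample SD), HDL is negated,
and the five z-scores are averaged (sum available by option).  The score's
cohort mean is zero by construction and this is asserted to < 1e−10 in
tests.  No log-transform is applied to triglycerides by default; the
composition is configurable via `ContinuousScoreSpec`.

## ROC and cutoff selection

Candidate thresholds are the midpoints between consecutive sorted unique
scores plus ∓∞ sentinels, with the rule score ≥ t ⇒ positive; this grid is
resolution-complete (every achievable confusion matrix appears).
Sensitivity and specificity come from exact counting.  The trapezoid AUC
over (1 − specificity, sensitivity) — with ROC points ordered
lexicographically so vertical runs contribute zero area and tie diagonals
contribute half — equals the Mann–Whitney concordance probability
(#concordant + ½·#tied)/(n₊·n₋); equality to 1e−12 against a brute-force
pairwise oracle is an acceptance-level test.

Interval estimation defaults to DeLong's structural-component variance
with a normal-approximation CI truncated to [0, 1] and a two-sided z-test
of AUC = 0.5; a stratified-bootstrap percentile CI (2000 resamples) is
available and is checked against DeLong on simulated data.  Degenerate
cases (perfect separation ⇒ zero variance) report a point interval and
p = 0 (or 1 when AUC = 0.5 exactly).

The screening cutoff maximizes Youden's J = sens + spec − 1.  Ties are
broken toward higher sensitivity, then the smaller cutoff — a fixed,
documented rule chosen because screening favours sensitivity.  On the
ascending threshold grid both rules select the first maximizer.  A curve
whose best J is 0 (uninformative score) is flagged degenerate and reports
the median score as its cutoff.  Reported sensitivity/specificity are
rounded to whole percent and LRs/J/cutoffs to two decimals only at export;
internal values keep full precision.

Stratified derivation produces one report per sex × age-group stratum per
index; strata failing preconditions (no cases, too few per class) are
listed as skipped with a reason rather than aborting.

## Association analysis

Partial correlation residualizes both variables on the covariates (with
intercept) by least squares and correlates the residuals; with k
covariates the p-value uses t with n − k − 2 degrees of freedom.  Sex
enters as a 0/1 indicator (female = 0).  With no covariates the function
reduces exactly to Pearson's r.  The implementation is verified against
the one-covariate recursion formula
(r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²)) to 1e−10 and cross-checked
against an independent implementation (pingouin) in tests.

LOWESS uses the classical defaults: tricube kernel, local linear fits over
the span-fraction nearest neighbours, span 2/3, no robustness passes
(bisquare iterations by option).  The smoothing itself is delegated to
statsmodels' lowess; the module adds precondition checks (n ≥ 10, ≥ 2
distinct x, span·n ≥ 3), grid interpolation, and an OLS R² of the same
data as the straight-line benchmark.

## Synthetic cohort generator

The generator emulates the stratum structure of the published cohort: six
sex × age-group strata (girls/boys 9–12, 13–17; women/men 18–25) at their
reported sizes (total 4673), with marginal means and SDs set to the
published Table-1 descriptives for twelve traits (age, weight, height,
waist, body-fat %, SBP, DBP, triglycerides, HDL, LDL, total cholesterol,
glucose).

Joint structure is a Gaussian copula: correlated standard normals (a
documented default correlation matrix — adiposity traits +0.55…+0.75
inter-correlated, HDL −0.2…−0.35 with adiposity, SBP–DBP +0.65, LDL–TC
+0.85, and conventionally signed smaller entries; positive definite with
minimum eigenvalue ≈ 0.08) are transformed per trait to:

- a truncated normal margin on the trait's bounds, with the location
  solved numerically so the truncated mean equals the target mean.  This
  matters for age, where the bin bounds sit ~1.2 SD from the mean:
  truncating without correction shifts the adolescent age mean by ≈ +0.25
  years, and doing the truncation by rejection would additionally bias
  correlated traits (weight, height).  Exact margins avoid both effects;
- a moment-matched log-normal margin for triglycerides, which are
  strongly right-skewed (SD/mean ≈ 0.5–0.6); a Gaussian margin truncated
  at zero would inflate the TG mean by several mg/dL.  Any trait can be
  switched between the two families per stratum.

Rejection sampling remains only for the joint SBP > DBP constraint and
residual log-normal tail excursions (both rare); an exhausted rejection
budget raises an error, which is how infeasible bounds surface.

Seeding: the master seed expands to per-stratum streams via
`SeedSequence([seed, crc32(stratum_key)])`, so adding or removing a
stratum never perturbs the others; planted effects use separate spawned
streams.  Identical (specs, seed) reproduce identical cohorts.

Planted effects assign labels Bernoulli(expit(slope·(index − θ))); an
infinite slope is a hard threshold, slope 0 the chance-level null.  The
recovery experiment (acceptance-tested) plants θ = 13.2 kg/m³ at slope 10
on the women-18–25 stratum, whose TMI distribution (mean ≈ 14.6, SD ≈ 2.3)
brackets θ; over 200 replicates of n = 2000 the median Youden cutoff lands
within ±0.15 of θ.  Note the Youden-optimal point for a logistic effect
sits at θ + logit(prevalence)/slope, here ≈ +0.09 — within the recovery
band, but a reminder that Youden cutoffs are prevalence-dependent.

What the generator does *not* emulate: the real cohort's correlation
structure (unpublished — the default matrix is a physiologically signed
fixture, not a fit), non-Gaussian shapes beyond TG's skew, measurement
error, intra-school clustering, or any TMI/FMI → MetS dose-response (MetS
labels on synthetic cohorts come from applying the criteria to the
simulated traits, or from planted effects).  Consequently tests on
synthetic data validate the *machinery* — classification logic, score
construction, ROC/Youden/DeLong correctness, pipeline determinism — not
the published AUCs or cutoffs, which derive from a private cohort and are
not reproducible from summary statistics.  Synthetic-cohort MetS
prevalences (≈ 7–18% per stratum under the default correlation matrix)
are only sanity-checked against a wide 2–30% corridor.

## Pipeline defaults

Descriptives use Welch's t by default (Student's by flag) and chi-square
without continuity correction (correction by flag).  Presentation rounding
(1 dp means, whole-percent sens/spec, 2-dp LRs, 3-dp AUCs) is applied only
at export.  Every output carries a provenance header (config hash
excluding the output path, seed, version) and no timestamps, so reruns
with the same config and seed are byte-identical.

## Known limitations

- Published LR values in this literature are computed from unrounded
  sensitivity/specificity; recomputing them from the printed whole-percent
  values reproduces the printed LRs exactly only where rounding happens to
  commute (asserted for the two strata where it does, and to ±0.05
  elsewhere).
- Published "J-Youden" columns in the source tables are not consistent
  with sens + spec − 1 computed from the same rows and are not used as a
  reference anywhere.
- The empirical-percentile fallback for paediatric criteria makes the
  waist/BP flags relative to the analyzed cohort; for population-referenced
  classification, supply external percentile tables.
- The continuous score's scale depends on the aggregation (mean vs sum)
  and the standardization scope; scores are comparable only within one
  analyzed cohort.
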