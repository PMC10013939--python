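# Methods

## The HBSR score

The Health Behavior Stroke Risk (HBSR) score summarizes five behavioral
risk domains for ischemic stroke in adults aged 18–54: smoking status,
body-mass index, physical exercise, diet, and alcohol use. Each factor is
graded low / moderate / high risk, worth 0 / 1 / 2 points; the five factors
sum to a total of 0–10, with 10 the worst attainable behavior. Totals of
6–10 define the *high* band, 0–5 the *low* band; the cut-off is a tested
constant of the score's definition, not a tunable.

Two factors are composites of two questionnaire answers each:

* **diet** = meal-salting habit + vegetable-consumption frequency. The
  adverse sub-answers are "salts ready-made meals before tasting" and
  "vegetables on fewer than 6 days/week".
* **alcohol** = use frequency + 7-day amount. The adverse sub-answers are
  drinking at least once a week and exceeding the sex-specific 7-day
  standard-unit limit (more than 8 units for women, 16 for men).

A composite grades high when both sub-answers are adverse, moderate when
exactly one is, low when neither is. With the low/moderate/high → 0/1/2
point bijection this makes a composite's points equal its count of adverse
sub-answers, which is what drives the monotonicity property tested in the
suite.

### The default answer→grade mapping

The full categorization table behind the score is not published in the
text available to us; the packaged default (shipped as
`hbsr/data/default_scoring.yaml`) is a reconstruction that honors every
published high-risk definition and the 0–10 range:

| factor   | low                      | moderate                      | high              |
|----------|--------------------------|-------------------------------|-------------------|
| smoking  | never                    | occasional, ex-smoker         | daily             |
| BMI      | < 25                     | 25–29.9                       | ≥ 30              |
| exercise | ≥ 2×/week                | 1×/week, 2–3×/month           | rarely or never   |
| diet     | no adverse sub-answer    | one adverse sub-answer        | both adverse      |
| alcohol  | no adverse sub-answer    | one adverse sub-answer        | both adverse      |

Open choices resolved here, all overridable through `ScoringConfig`
(YAML-serializable, `--scoring-config` on the CLI):

* **Ex-smokers and occasional smokers grade moderate.** Only daily smoking
  is named as high-risk; never-smoking is the unambiguous low state; the
  remaining categories carry residual risk.
* **Exercise 2–3×/week grades low** because the published high-risk
  definition is "less than twice a week".
* **Salting "when the food needs more salt" is non-adverse**: the flagged
  habit is salting before tasting.
* **Alcohol-excess comparison is strict** (`> 8` / `> 16`). The published
  definitions are internally inconsistent on this point (the table
  footnote reads `≥`); the comparison operator is a config switch
  (`alcohol_strict_inequality`).
* **Missing-factor policy `require_complete`** (default): a respondent
  missing any factor gets a missing total and is excluded from mean-score
  analyses, matching the complete-case handling used everywhere else. The
  alternative `treat_missing_as_low` scores missing factors as 0.

Because the mapping is a reconstruction, score-level outputs (means,
high-band prevalences) are structurally faithful but not numerically
identical to the original study's individual-level results.

## Statistics

* **Prevalence cells** are count / complete-case denominator, where the
  denominator counts respondents in the group × age-band stratum with a
  non-missing answer to that variable. Percentages are rounded half-up to
  one decimal, matching print conventions.
* **Two-proportion z-test**: pooled-variance normal approximation, two
  sided, no continuity correction; the statistic carries the sign of
  p̂₁ − p̂₂. Its square is the 1-df Pearson chi-square on the same 2×2
  (property-tested). A degenerate pooled proportion (0 or 1) returns
  statistic 0, p = 1.
* **Bonferroni**: adjusted p = min(1, m·p). The family size m defaults to
  the number of categories in a variable block when the block has more
  than two categories, and 1 for binary blocks (which print a single
  test). This reproduces every significance mark in the published
  prevalence table.
* **Odds ratios**: crude OR = ad/bc with the Wald 95% CI
  exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)); zero cells raise unless the
  Haldane–Anscombe +0.5 correction is enabled. Adjusted ORs come from an
  in-house logistic regression fit by iteratively reweighted least squares
  (Newton scoring): convergence when the largest score component drops
  below 1e-8 or the relative deviance change below 1e-10, at most 50
  iterations; coefficients exceeding |β| > 30 are treated as diverging and
  reported as perfect separation. Wald CIs are formed on the log-odds
  scale and exponentiated. The fit is cross-checked against an external
  GLM implementation in the test suite, and the single-binary-exposure fit
  reproduces the closed-form crude OR to 1e-6 relative tolerance.
* **Adjusted-model coding**: age continuous in years; sex as a male
  indicator; education and marital status reference-coded with *higher
  education* and *married/cohabiting* as references. Three model tiers are
  reported per exposure: crude; age + sex; age + sex + education +
  marital.
* **Mean scores**: two-sided t-test, Welch by default (Student optional),
  with normal-approximation 95% CIs (mean ± 1.96·sd/√n) per group.
* **Missing data**: complete-case per analysis throughout; no imputation.
* In the score analysis, the overall high-band comparison is reported
  unadjusted (a single planned comparison) and the four sex/age strata
  share one Bonferroni family (m = 4); raw and adjusted p are emitted side
  by side.

## The synthetic cohort generator

No individual-level data are publicly available, so the generator emulates
the two cohorts from their published summary statistics:

* **Behavioral marginals** per group × age band default to the published
  count / complete-case-denominator ratios for all seven variables
  (4 smoking + 3 BMI + 5 exercise + 2 vegetable + 3 salting + 5 alcohol
  frequency + 2 alcohol-amount categories).
* **Missingness** is injected completely at random (MCAR) per variable at
  the rate implied by each stratum's denominator (e.g. smoking among
  patients 18–44: 1 − 133/135).
* **Covariates**: group sizes 342 / 1789; male fractions 0.62 / 0.41; ages
  sampled uniformly on integer quartile bands calibrated to the published
  median/IQR (patients 47 [39–51], controls 37 [28–46]); education and
  marital mixes hit the published higher-education (20% vs 34%) and single
  (15% vs 22%) shares. The unpublished basic/secondary and
  married/divorced splits are fixed package defaults (patients
  0.25/0.55/0.20 education, 0.65/0.15/0.20 marital; controls
  0.15/0.51/0.34 and 0.62/0.22/0.16), chosen once as plausible for an
  Estonian adult population and not treated as calibration targets.
* **Dependence** between the seven behaviors uses a Gaussian copula: one
  latent multivariate-normal draw per respondent is thresholded at each
  variable's marginal quantiles. This separates marginals (published) from
  association (unpublished); the default latent correlation is the
  identity. Real behaviors cluster (smoking × alcohol, etc.), so the
  identity default understates the variance of the score distribution;
  direction-of-effect checks are therefore asserted, score-distribution
  shape is not.
* **Continuous refinements** are drawn inside the drawn category: BMI
  uniform within its class (18.5–25, 25–30, 30–40), vegetable days on the
  correct side of 6, and 7-day units strictly on the correct side of the
  sex-specific limit — so re-deriving the category from the continuous
  value recovers the drawn category exactly.
* **Randomness**: one root `SeedSequence` is split into per-group and then
  per-purpose child streams in a fixed, append-only order, so adding a new
  stream cannot perturb earlier draws; the same seed reproduces the cohort
  byte-for-byte.

What passing tests on synthetic data show: the pipeline's bookkeeping
(denominators, tests, models, report) is correct under known ground truth,
and the patient/control contrast in marginals propagates through the score
in the expected direction. What they do not show: anything about the true
joint distribution of behaviors, or the exact published score means —
those depend on individual-level data and the original categorization
table.

## Numerical choices and limitations

* Percentage rounding is half-up (printed style), applied only at display
  boundaries; CSVs carry full precision.
* BMI class boundaries are closed on the left ([25, 30) is the middle
  class). Direct BMI wins over height/weight-derived BMI; a disagreement
  beyond 0.5 kg/m² logs a warning.
* Age bands are inclusive: 44 → 18–44, 45 → 45–54.
* The patient-side pooled percentages in the source table are not exactly
  reproducible from the printed per-band counts (the implied overall
  denominators differ slightly); the package recomputes control-side
  aggregates, which do reproduce exactly, and never forces agreement on
  the patient side.
* Problem sizes used in the checked simulations: 50,000 observations for
  logistic parameter recovery, 100,000 respondents for marginal recovery,
  500 random tables for the crude-OR/logistic equivalence, 20 seeds at the
  default cohort sizes for the end-to-end direction check — sizes at which
  Monte-Carlo error is well inside the asserted tolerances while keeping
  the suite fast.
* Perfect separation is reported as an explicit error rather than fit with
  penalization; penalized (Firth) fits are out of scope, as are exact
  tests, survey weights, matching, and imputation.
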