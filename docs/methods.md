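# Methods

## Problem and overall procedure

`survscreen` implements a transcriptome-wide screen for genes whose
diagnostic expression level predicts right-censored overall survival in
multi-cohort studies — the motivating application is AML patients treated
with intensive chemotherapy followed by hematopoietic stem-cell
transplantation (HSCT), screened across three independent cohorts. The
procedure, per gene and per cohort:

1. estimate the time-dependent ROC curve of the gene's expression against
   survival status at a fixed horizon (default 36 months);
2. choose the optimal dichotomization cutpoint by Youden-J maximization and
   split the cohort into high and low expression groups (high = expression
   strictly above the cutpoint);
3. fit a univariate Cox proportional-hazards model on the group indicator
   and a multivariate model adding the clinical confounders (age, sex, WBC,
   transplant type, ELN risk category);
4. apply five filter gates, all strict inequalities: AUC > 0.5,
   sensitivity > 0.5, specificity > 0.5 at the chosen cutpoint, and
   two-sided Wald p < 0.05 for the group term in both Cox models.

Genes passing every gate in **every** cohort with a consistent effect
direction (sign of the adjusted group coefficient) form the cross-cohort
intersection. No multiple-testing correction is applied within a cohort;
the intersection across independent cohorts is the error control (a
Benjamini–Hochberg report is available separately via `bh_adjust` and is
clearly auxiliary). Intersection genes then feed the risk-refinement stage:
a base categorical risk system (ELN favorable/intermediate/adverse) is
augmented by the dichotomized marker and the stratification power of base
vs refined grouping is compared by log-rank.

## Survival machinery

All censored-survival estimators are implemented from first principles
(NumPy), with `lifelines` used only as an independent cross-check in the
test suite.

**Kaplan–Meier.** Standard product-limit estimator; censored subjects tied
with an event time remain at risk at that time. The reported median is the
earliest event time with survival ≤ 0.5, else `NOT_REACHED` (`inf`).

**Log-rank.** k-group observed-vs-expected chi-square over the pooled
distinct event times with the full hypergeometric covariance; the quadratic
form is taken over the first k−1 groups. On no-tie data the two-group
statistic equals the Cox score statistic of the group indicator exactly
(verified to 1e-6 in the tests).

**Cox proportional hazards.** Newton–Raphson maximization of the partial
likelihood with the Efron tie correction by default (Breslow available).
Covariates are internally centered and scaled for conditioning and the
coefficients transformed back. Convergence: absolute change in log partial
likelihood < 1e-9, at most 100 iterations, step-halving on overshoot.
Standard errors come from the inverse observed information; per-covariate
two-sided Wald tests are reported (matching forest-plot conventions).
Monotone-likelihood separation is detected (|standardized β| > 20 or
failure to converge) and flagged as `converged=False`; downstream gates
treat such fits as failures rather than trusting a runaway estimate.

**Time-dependent ROC.** Cumulative-cases / dynamic-controls estimator at a
fixed horizon t: cases are subjects dead by t, controls subjects observed
beyond t. Both are weighted by inverse probability of censoring (IPCW):
cases by 1/G(T⁻), controls by 1/G(t), where G is the Kaplan–Meier estimate
of the censoring distribution (event flags flipped). The AUC is the
weighted probability that a random case's marker exceeds a random
control's, ties counted half. With zero censoring this reduces exactly to
the Mann–Whitney concordance of the marker against died-by-horizon status,
which the tests exploit as an oracle. The estimator was checked to be
unbiased at large n against the uncensored truth.

**Optimal cutpoint.** Candidate thresholds are the observed marker values
restricted to a central quantile band (default 10th–90th percentile) to
keep both groups large enough for a stable Cox fit; the band is a config
knob. The cutpoint maximizes J = sensitivity + specificity − 1; exact ties
in J are broken toward the more balanced high/low split, then toward the
smaller cutpoint. Because only marker ranks enter, the chosen partition is
invariant under strictly increasing marker transforms.

A known small-sample behaviour of the empirical Youden maximizer is worth
stating plainly: with a few dozen cases and controls, the jagged empirical
ROC occasionally attains its maximal J at a high-specificity (or
high-sensitivity) corner where the other coordinate falls just below 0.5,
so a genuinely prognostic gene can fail the sens/spec gates in a given
cohort with roughly 5–10% probability at n ≈ 70–130. This is variance of
the estimator, not bias; it is visible in the seeded recovery experiments
and is the dominant reason a planted gene occasionally misses the
three-cohort intersection.

## Confounder encoding

Age and WBC enter continuously; sex as a male indicator (female
reference); transplant as an allo indicator (auto reference); ELN as two
indicators (intermediate, adverse) with favorable as reference. The ELN
dialect (2010 vs 2017) is recorded per cohort as metadata. Missing
covariates are handled complete-case per model: rows missing a covariate
are dropped from that Cox fit only, with a logged count; confounder
columns absent from a cohort are skipped with a single logged notice.

## Risk refinement

The default refinement mapping shifts marker-high patients one level
toward adverse (favorable→intermediate, intermediate→adverse,
adverse→adverse) and leaves marker-low patients in their base category.
The exact recategorization scheme used in practice varies between studies,
so the mapping is fully user-overridable via config; the default is a
declared interpretation, not a claim about any particular study. The
marker cutpoint for refinement reuses the screen's OS-derived optimal
cutpoint. Treatment-subgroup contrasts fit the marker indicator separately
per arm plus a pooled model with marker, treatment and marker×treatment
terms (chemotherapy-only as the reference arm). Because the pooled model
shares one baseline hazard across arms, its implied subgroup log-HRs agree
with the stratified per-arm fits only approximately; exact agreement would
need a treatment-stratified baseline, which is outside this package's
scope (no stratified Cox).

## Synthetic cohorts

The generator emulates the structure of AML transplant cohorts without
attempting to match any real cohort's marginal distributions or batch
structure:

- **Expression**: gene-wise Gaussian log-intensities, per-gene mean drawn
  uniformly from [4, 10], unit SD. Planted prognostic genes act on the
  continuous per-SD scale, so dichotomization performance has to emerge
  from the cutpoint machinery rather than being baked in.
- **Covariates**: age ~ Normal(55, 12) truncated to [18, 80] years;
  sex ~ Bernoulli(0.5); WBC log-normal (log-WBC ~ Normal(3, 0.8), units
  10⁹/L); transplant allo with probability 0.8; ELN categorical
  (0.25 / 0.50 / 0.25 favorable/intermediate/adverse); treatment all-HSCT
  unless an interaction spec assigns a chemotherapy-only arm.
- **Outcome**: Weibull proportional hazards, T = scale·(−log U / exp(lp))^(1/shape)
  with shape 1.1 and scale 36 months (median OS ≈ 26 months at linear
  predictor 0 — a realistic intensively-treated AML regime). The linear
  predictor sums planted-gene terms and confounder terms. Default
  confounder log-hazards: age 0.02/year above 55, male 0.10, 0.15 per SD
  of log-WBC, auto-HSCT 0.20, ELN intermediate 0.40 and adverse 0.90
  relative to favorable — modest magnitudes in line with published AML
  prognostic models.
- **Censoring**: administrative (independent uniform on [0, c_max]),
  with c_max calibrated in-sample so the realized censored count equals
  round(target·n) exactly; a subject is censored iff c_max·u < T, so the
  calibration reduces to placing c_max between order statistics of T/u.
  Uniform rather than exponential censoring because trial-style follow-up
  is administrative, and the calibration is then exact.
- **Multi-cohort**: per-cohort seeds are split deterministically from a
  master seed; cohorts share gene identities (so planted genes are shared)
  but have independent samples, sizes and censoring. The default trio is
  sized 69/77/134 to mirror the power regime of desk-scale three-cohort
  AML studies.

Every cohort ships with a `SyntheticGroundTruth` (planted gene ids and
coefficients, confounder coefficients, realized censoring, seed) that
suffices to regenerate it bit-identically.

What passing tests on these cohorts do **not** show: robustness to
non-proportional hazards, batch effects, heavy-tailed or bimodal
expression, informative censoring, or correlated genes — none of which the
generator produces.

## Problem sizes used in the shipped experiments

The seeded experiments run at the trio's study scale (69/77/134 samples,
200 genes) with 20 replicates for the recovery and null-calibration
properties, 50 replicates for refinement power, and n = 2000 single
cohorts for parameter-recovery and distributional checks. These sizes give
stable rates while keeping each experiment in the minutes range on one
core.

## Numerical and design choices

- Time unit is months everywhere; loaders convert from declared
  days (×12/365.25) or years (×12).
- Ties at a cutpoint go to the **low** group (high ⇔ strictly greater),
  which makes "cutpoint = observed value" well defined and matches the
  ROC threshold convention.
- Default ROC horizon 36 months (three-year mortality is the standard
  clinical window for intensively treated AML); a config knob, and
  `auc_trajectory` evaluates a horizon series with invalid horizons
  skipped under a warning.
- Gates use strict inequalities; `gate_mode="uni_only"` relaxes the
  multivariate p gate for sensitivity analyses (the multivariate fit is
  still reported).
- Exports format floats with shortest-repr (`repr(float)`) for data files
  (value-exact round trips) and `%.10g` for report tables; together with
  seeded simulation this makes pipeline outputs byte-stable, and re-running
  from a report's `manifest.json` reproduces the report byte-identically.
- Report writing is all-or-nothing: outputs are staged in a temporary
  sibling directory and atomically renamed, so aborts leave nothing
  partial behind.
- Fisher's exact test uses scipy's exact 2×2 implementation; contingency
  tables larger than 2×2 fall back to a seeded permutation method (scipy),
  keeping results deterministic.

## Known limitations

- No time-varying covariates, stratified or penalized Cox, or competing
  risks.
- The screen's per-cohort operations are embarrassingly parallel but run
  serially; transcriptome-scale inputs (~20k genes × 3 cohorts) take on
  the order of an hour on one core.
- The ROC horizon used for cutpointing is a single fixed time, not an
  integrated criterion; the choice is recorded in every result.
- DFS/EFS screening re-optimizes the cutpoint on the requested endpoint by
  default; to reuse the OS-derived cutpoint (the common reporting choice),
  pass it explicitly via `screen_gene(..., cutpoint=...)`.
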