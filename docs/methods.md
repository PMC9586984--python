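# Methods

## Model and estimand

Each stratum's outcome law is Bernoulli with probit link,
P(y=1 | x) = Φ(β₀ + β₁x), where y is binarized CES-D (>= 16 positive) and x
the AIS score. The probit (rather than logit) link follows the
dose-response tradition of estimating an ED50 under normally distributed
tolerances; the estimand here is its analogue ACPq = (Φ⁻¹(q) − β₀)/β₁, the
AIS score at which the estimated prevalence is q. ACP50 reduces to
−β₀/β₁. ACP values are real numbers and may fall outside the instrument's
0-24 range; they are deliberately not clamped, because the screening
semantics ("above" iff integer AIS >= cutoff) handle out-of-range cutoffs
naturally (nobody above, or everybody).

Stratification replaces multivariable adjustment: one single-predictor
model per subgroup controls the categorical confounders exactly and cannot
suffer multicollinearity, at the cost of smaller per-stratum n — which the
eligibility rules below address.

## Fitting and inference

The log-likelihood is maximized by Newton-Raphson on (β₀, β₁) with step
halving; for the probit likelihood the negative observed Hessian
X'diag(m(m+z))X (m the inverse Mills ratio at z = (2y−1)η) is positive
definite at any finite parameter value, so no Fisher-scoring fallback is
ever triggered in practice. Numerical choices:

- start at the intercept-only MLE (β₀ = Φ⁻¹(ȳ), β₁ = 0);
- converged when |Δloglik| < 1e-10 **and** max|gradient| < 1e-8; at most
  100 iterations;
- probabilities clipped to [1e-15, 1−1e-15] inside the likelihood;
- any |β| > 50 is declared (quasi-)separation: `converged=False`,
  `separated=True` — such models "cannot be constructed";
- standard errors from the inverse observed information at the optimum;
  Wald p-values p = 2(1−Φ(|β|/se)) and 95% CIs β ± 1.959963985·se (the
  z quantile is hard-coded so exported tables are stable);
- the mean ACP50 recovery error of ~0.03-0.05 AIS points at n = 50,000 per
  stratum (measured by the acceptance script) is sampling noise, not bias.

## Eligibility and exclusion of stratum models

Statuses per subgroup: `no_variation` (no positives or no negatives, or
fewer than `min_positives` = 5 members — too small for a stable fit),
`fit_failed` (non-convergence/separation), `slope_not_significant` (AIS
slope p > α = 0.05, two-sided Wald) and `fitted`. Only the slope's p-value
drives exclusion — a model without a usable slope cannot produce a cutoff —
and no multiple-testing adjustment is applied across strata, matching
screening practice where each subgroup's model stands alone. Excluded
strata carry no ACP, and are omitted from both the spectrum and the
screening evaluation population, so policy denominators refer only to
people whose stratum has a usable model.

## Stratum codes

A subgroup is named by a 6-character code over {0,1,x} in the fixed order
[MD history, working generation, female, lives alone, social isolation,
bereavement], with 1 the higher-risk category and x an unrestricted factor.
The mapping of digit positions to factors and the polarity are this
package's documented convention (configurable via the schema); published
6-digit subgroup labels do not state their digit order explicitly. When a
stratification leaves a factor inactive, its position shows `x` — e.g. the
32 five-factor subgroups of the MD-free population are coded `x#####`,
whereas published labels write a literal leading 0; this is a display
difference only.

## Derived-variable boundary conventions

CES-D >= 16 is positive (the cutoff score itself counts as positive);
LSNS-6 strictly below 12 is social isolation; age < 65 is working
generation (65-year-olds are retired); AIS >= 6 is the conventional
insomnia category. Raw totals and pre-derived binaries may coexist; a
contradiction raises an error rather than silently preferring one source.
Missingness is handled by stepwise complete-case filtering with an audit
ledger of before/after counts per stage; no imputation.

## Screening metrics and tuning

A policy screens each stratum at a cutoff (fixed AIS, or the stratum's ACP
at a common level q). Pooled over fitted strata, PPV = detected/screened is
identically the observed prevalence of the pooled above-cutoff category.
Published-table formatting uses round-half-up: prevalences to 3 decimals,
percentages to 1 decimal (0.4705 → 0.471), which binary-float "banker's"
rounding would not reproduce.

`tune_prevalence_level` scans q over [step, 100−step] percent (default step
0.1) and returns the q minimizing |detected(q) − target|, breaking ties
toward larger q, i.e. fewer screened. The published description of "closest
performance" does not pin down the criterion (its chosen levels slightly
under-detect their targets); absolute detection distance with the
frugal tie-break is this package's documented choice. With β₁ > 0 in every
stratum, cutoffs rise with q, so detected(q) and screened(q) are
non-increasing — the tuner's search space is well behaved.

## Synthetic-data generator

`synth.generate_cohort` draws the six risk factors independently
(defaults: MD 5%, working 55%, female 60%, lives alone 10%, isolation 30%,
bereavement 30% — plausible community-cohort marginals), AIS from a
discretized exponential with scale 3.5 (≈18% of records at AIS >= 6,
echoing the scale of the motivating cohort; illustrative, not an estimate),
and the outcome from the per-stratum probit law. The default additive
coefficient rule (base intercept −2.2, slope 0.25, MD shift +0.625, small
positive shifts for the other risk factors) places ACP50 at 8.8 AIS points
without MD and 6.3 with MD. Each seed is spawned into per-stage child
streams so editing one stage's configuration leaves the others' draws
intact; identical config + seed yields byte-identical CSV.

What the generator does **not** emulate: correlation among risk factors
(an optional shared-latent hook was considered and left out — none of the
tested properties need it), age as a continuous confounder of the AIS-CES-D
relation, item-level questionnaire structure, and informative missingness.
Passing tests therefore demonstrate that the estimator, inversion, ordering
and tuning machinery are correct under the model's own assumptions — not
that the probit-in-AIS law holds in any real population.

## Bundled count tables

Three TSV tables transcribe the published subgroup counts of the 8,440
person cohort study the method comes from (MD-stratified totals and ACP50
cells; ACP50/ACP75 under three- and five-factor stratification on the
7,021-person evaluation population; fixed AIS-6 and tuned ACP policies).
All printed prevalences, PPVs and comparison percentages reproduce from
these counts under the rounding conventions above — with one exception the
tests document: a text figure of 90.4% whose underlying ratio (1407/1555)
rounds to 90.5%.

## Problem sizes

The test suite and acceptance script size their simulations for tight
statistical margins: 50 datasets of n=200 for grid-dominance of the MLE
(201×201 grid over [−5,5]×[−1,1]), n=50,000 per stratum × 10 seeds for
ACP50 recovery (mean |error| < 0.15 AIS points with a large margin),
n=100,000 for per-score calibration (uniform AIS so every score carries
~4,000 records), and n≈12,000 for the engineered 32-stratum exclusion
scenario. In that scenario the five flat-slope strata have a truly zero
slope, so each exclusion is a null p-value draw; the bundled test fixes
the seed, while the acceptance script reports whatever count its seeded
draw produces.

## Known limitations

- CES-D positivity is a surrogate outcome; PPV here is not PPV against a
  clinical depression diagnosis.
- Wald inference is first-order; in very small strata the slope test that
  drives exclusion is itself unstable (hence the `min_positives` floor).
- The registry fits strata independently; no shrinkage or borrowing across
  strata, so tiny subgroups are dropped rather than stabilized.
- Per-stratum ACP cutoffs inherit the model's extrapolation: in strata with
  few high-AIS members, ACP75 may rest on a thin data region.
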