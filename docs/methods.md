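# Methods

## The models

### Univariate variance decomposition

A twin pair's scores are modeled as bivariate normal with a common mean
and covariance determined by the biometric structure: additive genetic
effects (A) correlate 1.0 across MZ co-twins and 0.5 across DZ co-twins,
shared environment (C) correlates 1.0 in both, non-additive genetic
effects (D) 1.0 and 0.25, and non-shared environment (E, which absorbs
measurement error) 0. The fitted families are ACE, ADE, AE, CE and E;
means are equated across twin order and zygosity (the saturated-model
ladder in `saturated_ladder` supports testing that assumption first).
The likelihood depends on the data only through per-zygosity sufficient
statistics, so a fit costs the same at any sample size.

Parameterization is through path coefficients (components are squares),
which enforces non-negative variance shares structurally. A consequence
is that the `c = 0` boundary makes the likelihood-ratio test against the
reduced model conservative under the plain chi-square reference; the
plain reference is nevertheless the default (matching common practice in
twin analyses), with the 50:50 chi-square mixture available via
`lrt(..., boundary=True)`.

### DeFries–Fulker extremes analysis

Probands are the highest-scoring `p`% of individuals (the severe tail of
the symptom scale); selection is computed on ranks, so any strictly
monotone re-expression of the scores yields the same proband set, and
ties at the cut-off are all included. Scores are affinely transformed to
put the population mean at 0 and the proband mean at 1; the transformed
co-twin means then read like twin correlations. Group heritability h²g
is estimated two ways:

* **regression** — the augmented DF regression `C = B1·P + B2·R + A` on
  double-entered data (each proband contributes one row; concordant
  pairs appear twice), with h²g the partial coefficient on the
  coefficient of relationship R and cluster-robust (pair-level) standard
  errors to account for the double entry;
* **model-fitting** — maximum likelihood for the implied means model
  `E[C] = h²g·R + c²g` (plus a proband-score covariate) with
  per-zygosity residual variances, and profile-likelihood CIs.

The two routes agree to well within Monte-Carlo noise (mean absolute
difference ≈ 0.002 at the default study size). h²g is clipped to [0, 1]
for reporting; the raw value is kept in `h2g_raw`. The group
shared-environment share c²g can be estimated (`model="ACE"`) or fixed
to zero (`model="AE"`); the AE variant has substantially lower sampling
variance at extreme percentiles (at the 1st percentile only ~30
probands remain) and matches the family of models that fit such data
best, so calibration summaries use it.

### Liability-threshold models

Binary outcomes arise from a standard-normal liability exceeding a
threshold. Per-zygosity 2×2 concordance tables are fit by multinomial
maximum likelihood with cell probabilities given by bivariate-normal
orthant integrals at liability correlation `a² + c²` (MZ) or
`½a² + c²` (DZ). Thresholds are equated across twin order and zygosity
by default, mirroring the equating of means and variances on the
continuous side; per-zygosity thresholds are available as an assumption
check. Probandwise concordance is `2C/(2C + D)` over concordant-affected
(C) and discordant (D) pairs.

A table with an empty concordance cell (e.g. no concordant-affected
pairs in one zygosity) leaves the likelihood flat all the way to the
correlation boundary; `tetrachoric` detects this, reports the estimate
*at* the boundary (±1.00) and flags it, rather than returning an
arbitrary interior point of the flat region.

### Joint categorical–continuous model

One continuous trait and one threshold trait per twin give a 4-variate
normal `(y₁, y₂, l₁, l₂)` with a correlated-factors A/C/E structure
(cross-trait factor correlations rA, rC, rE; cross-twin cross-trait
covariance `R·rA·a₁a₂ + rC·c₁c₂`). The correlated-factors
parameterization is used rather than a Cholesky because rA and rE are
then direct parameters with direct profile CIs; the two are
likelihood-equivalent at two traits. The per-pair likelihood factorizes
as the bivariate-normal density of the continuous pair times the
conditional orthant probability of the liabilities given the scores;
because the model covariance is constant within zygosity, the
conditional covariance is too, and one likelihood evaluation reduces to
two small matrix solves plus a vectorized orthant computation.

Derived quantities obey the identities
`r_PH = rA·a₁a₂ + rC·c₁c₂ + rE·e₁e₂` (standardized paths) and
bivariate heritability `= rA·a₁a₂ / r_PH` exactly at the estimates.
Non-additive (D) cross-trait structure is not modeled: although observed
MZ/DZ cross-twin cross-trait ratios can exceed 2, a univariate D
component is absent in the continuous trait under the AE best fit, so a
cross-trait D influence is implausible; the joint ADE model is out of
scope. The liability threshold is estimated freely rather than fixed to
an external prevalence — fixing it is a special case that would only
sharpen the threshold at the cost of an extra input. The continuous
trait is z-standardized (of the log score) before fitting, making all
reported quantities scale-free.

## Numerical choices

* **Bivariate-normal CDF**: Owen's-T closed form (`scipy.special.owens_t`),
  deterministic with absolute error below 1e-13 (validated against
  adaptive double quadrature); never Monte Carlo, so every fit is exactly
  reproducible. Infinite thresholds are clamped to ±40 SD, where the
  univariate normal CDF is exactly 0/1 in double precision.
* **Optimization**: Nelder–Mead followed by BFGS from several documented
  starting points (moment-informed plus neutral and perturbed starts);
  a final simplex polish that fails to improve the objective by more
  than 1e-6 defines convergence. Invalid parameter regions return a
  large finite penalty rather than infinity to keep simplex arithmetic
  clean.
* **Confidence intervals**: profile likelihood at the chi-square(1) 95%
  cutoff (3.841), inverted by bracketed root-finding; this respects the
  boundary at 0 for variance shares, unlike delta-method intervals.
  Endpoints satisfy `-2LL(endpoint) - (-2LL)(MLE) = 3.84` to 1e-3.
* **Information criteria**: `AIC = -2LL + 2k`; `BIC = -2LL + k·ln(N)`
  with N the number of twin *pairs* by default (the pair is the
  independent sampling unit); individuals are available via
  `bic_n="individuals"` since both conventions appear in the literature.
* **Model selection**: default policy prefers the most reduced model not
  significantly worse than its comparison model by LRT at α = 0.05,
  tie-broken by lowest BIC; a pure lowest-BIC policy is available, and
  disagreements between policies surface as different return values
  rather than being silently resolved.

## The synthetic-data generator

`SimConfig` defaults define the emulated study conditions: 1481 female
same-sex pairs (768 MZ, 713 DZ), an AE continuous trait with h² = 0.65,
diagnosis prevalences around 2.4% (AN-like), 3.3% (other-ED-like) and
5.7% (any), and cross-trait correlations rA = rE ≈ 0.26–0.60 depending
on scenario. Simulation is by explicit latent factor draws (A shared
structurally across MZ co-twins, half-shared for DZ; C shared within
pair; E independent) rather than direct multivariate-normal pair draws —
distributionally identical, but the sharing is structural and extends
cleanly to the bivariate case, where the factor construction reproduces
the Kronecker covariance `twin-sharing ⊗ trait-correlation` exactly.
If a D component is ever simulated, DZ non-additive sharing is fixed at
the standard 0.25; D is off by default since AE structures fit the
emulated data best.

The bounded 1–6 symptom scale is emulated by a Johnson-SB map: the
log-odds of the score's position within its support is linear in the
standard-normal phenotype. With the lower bound fixed at 1 and
(γ, δ, span) calibrated by Gauss–Hermite quadrature, the transform
reproduces the target population moments (mean 2.66, s.d. 0.90, skew
0.57) exactly, stays strictly monotone (no clipping ties — a hard-
clipped shifted lognormal would put ~1.7% of mass on the floor), keeps
the support inside [1, 6] (calibrated upper end ≈ 5.90), and a log
transform restores approximate symmetry, matching how such scores are
analyzed. The exact mechanics of the real instrument's skew are not
known beyond three moments, so the family is a modeling choice, recorded
in the ground-truth manifest.

Seeding: one master seed; named substreams are derived with
`numpy.random.SeedSequence(seed, spawn_key=(stream,))`, so each
simulation mode is bit-reproducible and independent of the others.

What the generator does *not* emulate: item-level response structure
(totals only), sex-limitation and age effects, attrition, registry
linkage error, and any non-normality of the latent liability. Passing
tests therefore demonstrate estimator correctness under the stated
generating model, not robustness to violations of it.

### Phenotype construction rules

The total symptom score is the mean of all answered items across the
three subscales (7 + 7 + 9 items, responses 1–6), computed only when
each subscale has at least 75% of items answered (≥ 6/7, ≥ 6/7, ≥ 7/9);
how answered items are averaged when a single item is missing is not
further specified by the instrument's scoring rule, so the mean of
answered items is used and documented here. Diagnosis classification
pools three sources (register ICD codes, parent-reported treatment,
self-reported regular purging) with AN precedence; missing source flags
count as "not ascertained = not a case", because parent reports cover
only ~72.5% of the emulated cohort, and per-source availability is
reported separately. Register codes are accepted with or without a dot;
excluded feeding/eating codes are dropped with a logged count. Report
percentages round half-up to one decimal.

## Problem sizes used in tests and the acceptance script

Replicate counts are scaled to what stabilizes each summary: 100 cohorts
for heritability bias/coverage and the DF route-agreement and
severity-trend properties (cheap fits), 10–15 for liability and DF
recovery checks, 50 for the joint-model scenarios (the rare-outcome AN
scenario has only ~70 affected individuals per cohort, so its
cross-trait correlation estimate has sampling s.d. ≈ 0.085 and the mean
over 50 replicates is reported), and 12 for the joint recovery test.
Large-n asymptotic checks use 12k–50k pairs per zygosity. The
bivariate-heritability summary in the acceptance script evaluates the
ratio identity at the replicate-mean component estimates rather than
averaging per-replicate ratios, avoiding small-sample ratio bias.

## Known limitations

* Boundary-aware inference is limited to flagging: estimates pinned at a
  boundary are reported and flagged, but mixture-reference CIs are not
  constructed.
* The joint model handles exactly one continuous and one binary trait;
  trivariate models and multi-threshold (ordinal) liabilities are out of
  scope.
* Regression-route h²g standard errors are cluster-robust but
  asymptotic; at the 1st percentile (~30 probands) profile-likelihood
  CIs from the model-fitting route are more trustworthy.
* `fit_saturated` with equality constraints and all ACE-family fits
  assume complete pairs; pairs with any missing value are dropped
  (listwise), matching an analysis restricted to complete responders.
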