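# Methods

## Index construction

Let x_{gs} be the log2-scale expression of probe g in sample s, z-scored
within its dataset (per probe: subtract the mean over samples, divide by
the sample standard deviation, ddof = 1). Given disjoint probe sets P and
N, the per-patient index is

    score_s = (1/n_P) Σ_{i∈P} z_{is} − (1/n_N) Σ_{j∈N} z_{js},

with n_P and n_N the counts of set members actually present on the
platform. Standardization is strictly per dataset; merged multi-cohort
matrices concatenate per-dataset z-scores and are never re-standardized.
Because the inputs are z-scores, the score has mean ≈ 0 over the
standardization cohort, is exactly antisymmetric under swapping P and N,
and carries no intrinsic responder threshold (none is emitted).

P and N come from consensus co-expression discovery. In each discovery
cohort every probe is Pearson-correlated against the target probe; with
n probes and tail fraction f (default 0.01), the k = max(1, floor(f·n))
largest-r probes form the cohort's top set and the k smallest its bottom
set. Boundary ties are broken by a single deterministic ranking on
(r, probe id), which also guarantees the two tails are disjoint for
f < 0.5. P is the intersection of all top sets, N of all bottom sets; a
probe in the top tail of one cohort and the bottom tail of another has no
consistent sign and is excluded from both (logged). The target correlates
1.0 with itself, so it survives every top set; `include_target`
(default true) controls whether it is kept in P. Pearson r is invariant
to positive per-probe affine transforms, so discovery behaves identically
on raw log2 intensities and z-scores.

Indices for different targets are combined by an unweighted per-sample
sum (a `mean` rule is available). The sum is the natural default for
multi-agent regimens: it preserves the per-unit odds-ratio reading of each
component and widens the score range accordingly.

## Validation battery

* **AUC** is computed as the Mann–Whitney statistic U/(n₁·n₀) with ties
  counted ½, oriented so higher scores favor pCR; significance is the
  two-sided tie-corrected normal-approximation Mann–Whitney test of
  AUC = 0.5 (scipy's asymptotic method, with continuity correction). This
  choice of p-value method is a documented convention; AUC itself is exact
  and invariant under strictly increasing score transforms.
* **Group comparison** is a two-sided t-test of scores between pCR and RD.
  Under the default `auto` rule, Welch's correction is used when a
  two-sided F-test of variance equality rejects at 0.05; `student` and
  `welch` overrides are available, and the decision is logged.
* **Logistic regression** (statsmodels, Newton MLE) reports OR = exp(β)
  with 95% Wald intervals and two-sided Wald p-values. Encoding
  conventions: age is rescaled to decades before fitting, grade enters as
  ordinal numeric (1–3), ER status and nodal status as 1 = positive
  indicators. Rows with missing outcome or missing used covariates are
  dropped and counted. Multivariate fits also report the AUC of the fitted
  probabilities. Perfect separation raises an explicit error naming the
  diverging term (detected via statsmodels' separation diagnostics plus a
  coefficient-magnitude guard); non-convergence raises with the optimizer
  diagnostics.
* **Predictor comparison** is one-way ANOVA plus Tukey HSD over
  user-supplied replicate performance values (e.g. per-dataset AUCs); the
  replicate unit is deliberately the caller's choice. All tests are
  two-sided at α = 0.05.

## Synthetic cohorts

The generator emulates the minimal structure under which co-expression
discovery is meaningful. Per cohort: latent activity a_s ~ N(0,1); target
probe = μ_t + a_s + ε (ε sd `target_noise_sd`, default 0.5); positive
module gene g = μ_g + b_g·a_s + ε (b_g ~ U(0.5, 0.9), ε sd `noise_sd`
default 1.0); negative genes carry −b_g·a_s; background genes are pure
noise; baselines μ_g ~ U(6, 12) log2 units. Response is
Bernoulli(logistic(γ₀ + γ₁·a_s)) with γ₀ = logit(0.2) — matching the
~19–21% pCR prevalence of neoadjuvant validation cohorts — and γ₁ = 1 by
default. The true module (probe identities) is shared across cohorts while
loadings, baselines and noise are redrawn, so cross-cohort intersection is
meaningful. Defaults are three cohorts of 200 patients × 2000 probes with
a 50/25 signed module.

The implied population correlation between a positive module gene and the
target is b / (√(b² + noise_sd²)·√(1 + target_noise_sd²)); tests verify
the empirical correlations against this closed form. Because the outcome
depends on the latent activity rather than on measured expression, every
expression-based predictor faces an irreducible noise ceiling — mirroring
the biological claim that target activity drives response.

Covariates (age, ER, grade, node) are generated from documented marginals
(age N(50,10) truncated at 25; ER positive 0.43; node positive 0.72;
grade probabilities 0.06/0.38/0.56) with optional linear dependence on the
latent activity (logit shift for binary covariates, cumulative-logit shift
for grade); dependence defaults to 0.

What the generator does *not* model: probe-level Affymetrix noise
structure, batch/platform effects, probe cross-hybridization, replicate
profiling, or survival endpoints. Passing tests therefore demonstrate the
statistical machinery is correct under the assumed latent-factor model,
not that real microarray cohorts satisfy that model.

## Numerical and interface choices

* Standard deviation uses ddof = 1 throughout (conventional for
  expression z-scores); zero-variance probes are dropped with a warning at
  standardization and excluded from correlation — real series contain flat
  control probes, so this is not an error.
* Standardizing an already-standardized matrix is a hard error: silent
  double transformation corrupts scores.
* Missing expression values are rejected at load (strict mode); clinical
  missing values are explicit (`NA`/empty) and tolerated everywhere except
  the validation response, where affected samples are dropped and counted.
* Score coverage: an index set entirely absent from a platform contributes
  0 with a warning (the other set carries the index — expected across
  array generations); a set *partially* present below 50% coverage
  (configurable) is an error, since partial loss usually means the wrong
  matrix. Both sets absent is an error.
* Merging requires per-dataset-standardized inputs, exact probe-id
  intersection, and globally unique sample ids; replicate handling for
  replicated designs is left to the caller (average or treat as
  independent before loading), since either convention is defensible.
* All pipeline outputs are deterministic given inputs and seed; run
  manifests record sha256 hashes of inputs and outputs and contain no
  timestamps, so reruns are byte-identical.
* File formats round-trip exactly: floats are written with `repr` and
  parsed with correctly-rounded conversion.

## Problem sizes used by tests and the acceptance script

Discovery recovery runs on three cohorts of 200 × 2000 with the 50/25
module (precision of the recovered index ≥ 90% against ground truth;
recall rises with loading strength). Null calibration uses one
2000-patient cohort for the AUC band and 200 replicates of 300 patients ×
200 probes (20/10 module) for the t-test rejection rate. Odds-ratio
recovery uses 50 replicates of n = 2000 with per-unit log-odds 0.285
(OR 1.33) fitted on the latent activity; the gene panel is kept small
there because the fit does not consume expression. These sizes are the
package's standard demonstration conditions.

## Known limitations

* Probe-to-gene annotation, RMA normalization of raw arrays, and
  cross-platform probe mapping beyond exact id intersection are out of
  scope; inputs must be normalized probe-level matrices sharing an id
  space.
* The consensus-intersection rule has no false-discovery control beyond
  the rank cutoff; with many discovery cohorts the index can empty out
  (raised as an explicit "no consensus" error).
* Wald intervals and the asymptotic Mann–Whitney p-value are large-sample
  approximations; for very small validation cohorts exact methods would be
  preferable.
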