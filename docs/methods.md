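# Methods

This note documents the statistical model, the conventions the package
commits to where the underlying methods literature is ambiguous, the
synthetic-data generator, and the numerical choices. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Data model

Each patient c contributes a pair of binary outcomes (y₁, y₂) under
interventions k = 1, 2; either outcome, but never both, may be missing
(patients with both observations missing carry no information under the
models used here and are rejected at ingestion — a lenient reader mode
counts and drops them with a warning instead). Observed frequencies live in
a 3×3 table: complete-pair cells n₀₀, n₀₁, n₁₀, n₁₁ and half-observed
margins n₀ₓ, n₁ₓ (y₂ missing) and nₓ₀, nₓ₁ (y₁ missing).

Missingness is assumed MAR: it may depend on the intervention arm but not on
the outcome. Under MAR both risk-difference estimators are unbiased:

* complete-case: θ̂_cc = (n₁₀ − n₀₁)/n₊₊;
* all-observed: θ̂ = (n₁₊+n₁ₓ)/(n₊₊+n₊ₓ) − (n₊₁+nₓ₁)/(n₊₊+nₓ₊).

Counts are sufficient for every procedure in the package, so all four
methods accept the aggregated table; pair-level input is tabulated on
ingestion.

## The four interval procedures

All intervals are reported at two-sided level 1 − 2α (default 90% for
one-sided α = 5%), and all methods share one decision surface: reject
H₀: θ ≤ −δ iff the interval's lower bound exceeds −δ. This puts the score
test and the three Wald-type intervals on the same footing in the
simulation harness.

### Score test and score CI (complete pairs)

The score statistic standardizes θ̂_cc + δ by the restricted-MLE null
variance σ̃² = [(p̃₁,₀₁ + p̃₁,₁₀) − δ²]/n₊₊, where the restricted
discordant-probability estimates at the boundary θ = −δ solve the quadratic
2p² + ã₁p + b̃₁ = 0 with ã₁ = −θ̂_cc(1−δ) − 2(p̂₀,₁+δ) and
b̃₁ = δ(1+δ)p̂₀,₁ (larger root, p̃₁,₁₀ = p̃₁,₀₁ − δ). At δ = 0 the squared
statistic is exactly McNemar's chi-square.

The CI inverts the same standardized score over candidate values θ₀,
substituting the boundary value −θ₀ for −δ in the restricted-variance
formulas (the literature states the restricted fit only at the hypothesis
boundary; this substitution is what makes the interval construction
well-defined and keeps it dual to the test). The standardized score is
monotone decreasing in θ₀, so each endpoint is found by bisection
(tolerance 1e−10) on [−1, θ̂_cc] and [θ̂_cc, 1]; where the restricted
variance vanishes the score is continued as ±∞ with the sign of
θ̂_cc − θ₀, which resolves fully concordant tables without a special case
(such tables yield one-sided information; a table with no complete pairs
raises instead of returning a spurious interval). Endpoints are clipped to
[−1, 1] after root finding.

The asymptotic sample-size routine uses the statistic's normal limit:
power(n) = Φ([(θ+δ)√n − z_α√v₀]/√v₁) with v₀ the population restricted
variance at the boundary and v₁ = p₁₀ + p₀₁ − θ² the unrestricted variance,
returning the smallest integer n reaching the target. For a complete-case
analysis with a fraction 1 − p_complete of patients losing one observation,
the complete-data n is divided by p_complete and rounded up.

### Multiple-imputation Wald CI

Missing outcomes are imputed from the two cross-outcome logistic models
logit P(y₁=1|y₂) and logit P(y₂=1|y₁) fitted on complete pairs. Because
both variables are binary these are saturated 2×2 fits with closed-form
MLEs (the slope is the log odds ratio) and closed-form observed
information; a zero cell is handled by adding 0.5 to each complete-pair
cell for model fitting only (needed routinely at n = 20). Each of m = 10
imputations draws one coefficient vector per model from the asymptotic
normal N(MLE, inverse information) — per imputation, not per record — and
imputes each missing outcome Bernoulli at the implied probability
(equivalently, comparing the predicted score to a uniform draw). Per
completed dataset the complete-data estimator θ̂ and the unrestricted ML
variance σ̂² = [(p̂₀,₁+p̂₁,₀) − θ̂²]/n are computed on all n pairs; Rubin's
rules pool them (total variance = within + (1+1/m)·between) and the
interval is θ̄ ± z_α√total. The reference distribution is normal by
default, matching the Wald construction; a flag switches to the
Barnard–Rubin t as a sensitivity option. Pooling is on the natural scale of
θ. With no missing data the procedure collapses exactly to the single
Wald interval.

### Hybrid Wilson-based CI

The point estimate is the all-observed θ̂. Margin estimates
p̆₁,₊ = (n₁₊+n₁ₓ)/(n₊₊+n₊ₓ) and p̆₊,₁ = (n₊₁+nₓ₁)/(n₊₊+nₓ₊) use every pair
in which the respective outcome is observed (the row-margin denominator is
the pairs with y₁ observed and the column-margin denominator the pairs with
y₂ observed; a source that prints nₓ,₊ in the row-margin denominator is
treated as a typo). Wilson score bounds (l, u) for each margin are computed
at two-sided level 1 − 2α so the same quantile z_α appears in the interval
and in the back-solved variances (p−l)²/z² and (u−p)²/z². The limits are

    L = θ̂ − √[(p̆₁,₊−l₁,₊)² + (u₊,₁−p̆₊,₁)² − 2ρ̂(p̆₁,₊−l₁,₊)(u₊,₁−p̆₊,₁)]
    U = θ̂ + √[(u₁,₊−p̆₁,₊)² + (p̆₊,₁−l₊,₁)² − 2ρ̂(u₁,₊−p̆₁,₊)(p̆₊,₁−l₊,₁)]

with ρ̂ the within-patient correlation, estimated as the phi coefficient of
the complete pairs (the natural Pearson correlation of two binaries and the
quantity the generator's ρ targets; degenerate margins give ρ̂ = 0 with a
warning). A negative radicand (possible at extreme ρ̂) is clipped to zero
with a warning rather than raised. Interval width is non-increasing in ρ̂.

### GEE delta-method CI

The marginal model logit P(Y=1|k) = β₀ + β₁·I(k=2) is fitted by generalized
estimating equations with an exchangeable working correlation: complete
pairs are clusters of size two, half-observed pairs singleton clusters.
Since the marginal success probability given k does not depend on the
missingness indicator under MAR, singletons contribute valid information to
β̂ (they contribute none to the working-correlation estimate, which is the
standard moment estimator over the Pearson-residual cross-products of
size-two clusters, denominator n₊₊ − 2, clipped to |α̂| ≤ 0.99 to keep the
2×2 working matrix invertible). The dispersion φ is fixed at 1 (binomial
variance); Pearson moment estimation is available behind a flag. Fisher
scoring alternates with the moment update; starting values are the
independence-fit group-proportion logits; convergence is a relative β step
below 1e−10 (at most 100 iterations), and the estimating-equation residual
norm is reported. Arms with constant outcomes raise a separation error.

Covariances: model-based I₀⁻¹ and sandwich I₀⁻¹I₁I₀⁻¹, with I₁ accumulated
from per-cluster empirical residual outer products; the sandwich ("robust")
covariance is the default. The risk difference is
θ̂ = expit(β̂₀) − expit(β̂₀+β̂₁) with delta-method gradient
(μ̂₁(1−μ̂₁) − μ̂₂(1−μ̂₂), −μ̂₂(1−μ̂₂)) and Wald interval θ̂ ± z_α·SE — a
source display that multiplies z by a variance symbol is read as the
standard error, the only dimensionally consistent choice. No small-sample
sandwich correction (Mancl–DeRouen type) is applied; the harness is meant
to exhibit the uncorrected sandwich's small-n behavior.

Clusters with identical design and outcome are collapsed into weighted
cluster types (at most eight in the covariate-free design), so a fit costs
O(1) in n. The design abstraction admits extra covariate columns, though
only the treatment indicator is exercised.

## Synthetic data

A correlated binary pair with marginals (p₁, p₂) and Pearson (phi)
correlation ρ has its joint law fully determined by
p₁₁ = p₁p₂ + ρ√(p₁(1−p₁)p₂(1−p₂)) within the Fréchet bounds, so pairs are
drawn directly from the four-cell multinomial; this is distributionally
identical to Gaussian-threshold generators (users should not expect
stream-level equality with such tools, only equality in law). Missingness
is one per-pair trinomial indicator with probabilities
(p_miss1, p_miss2, 1−p_miss1−p_miss2) removing y₁, removing y₂, or keeping
the pair — at most one observation is ever removed, and removal never
depends on outcomes, making the mechanism MCAR for balanced and MAR for
arm-dependent probabilities. Generation and missingness use separate
sub-streams of a per-scenario seed, so toggling missingness leaves the
underlying pair draws unchanged.

Study defaults mirror the reference design: marginals 0.8, within-patient
correlation ρ ∈ {0, 0.37, 0.5}, n ∈ {20, 30, …, 100, 200, 300, 400, 507},
missingness ∈ {(0,0), (0.15,0.15), (0.25,0.25), (0.1,0.3)}, one-sided
α = 5%, 10 000 replicates — 468 scenarios in the full grid. The
concordance-0.8 design (p₁₁+p₀₀ = 0.8 at marginals 0.8) corresponds to
ρ = 0.375 exactly; 0.37 is the conventionally quoted rounding, and the
grid uses 0.37 while the asymptotic sample-size reference design uses the
exact 0.375 (the rounded value yields 510 rather than 507 from the same
formula).

**Sign convention for boundary scenarios.** With H₀: θ ≤ −δ, type-I-error
scenarios generate data at the null boundary θ = −δ: the deficient arm's
marginal is 0.8 − δ and the other stays at 0.8. Descriptions that quote a
positive "true risk difference δ = θ" at the boundary refer to the same
configuration with the arms' roles interchanged; the harness takes the
margin and the signed true θ explicitly.

What the generator does *not* emulate: covariates, outcome-dependent
(MNAR) missingness, patients missing both outcomes, more than two
interventions, or between-center clustering. Passing simulation tests
therefore validate the procedures under exchangeable correlated Bernoulli
pairs with arm-level missingness — not robustness to any of the above.

## Simulation harness

Per scenario, replicates are drawn at the count level (a single
eight-category multinomial per replicate, split by the missingness
indicator), and the four procedures run through vectorized batch
implementations that the test suite verifies against the scalar reference
API table by table. Power and coverage are the proportions of replicates
rejecting H₀ and covering the true θ; the Monte-Carlo SE of a proportion is
√(p̂(1−p̂)/n_sim); width is the mean upper-minus-lower. Replicate-level
failures (no complete pairs; GEE separation or non-convergence) are
excluded from denominators and reported per method — at n = 20 with heavy
missingness, GEE separation affects a few percent of replicates, and this
accounting choice visibly affects small-sample type-I estimates (software
that returns divergent fits with enormous standard errors instead
effectively counts those replicates as non-rejections). Per-scenario seeds
derive from (seed, scenario index) via `numpy.random.SeedSequence`, so grid
results are independent of execution order and worker count.

The simulation-based sample-size search estimates power on an n-grid
(default 500–700 in steps of 2) and applies the conservative monotone rule:
the smallest n whose power exceeds the target with every larger grid point
also exceeding it. By default every n reuses the same random streams
(common random numbers), which removes most replicate-level noise from the
shape of the power curve; the residual Monte-Carlo uncertainty of the
crossing point is still on the order of ±(MCSE/slope) ≈ ±16 patients at
2000 replicates and ±7 at 10 000 for the reference design, which is why
repeated searches with different seeds scatter by several grid steps — a
property of the rule itself, not of the implementation.

## Numerical choices and degenerate inputs

* Score-CI bisection tolerance 1e−10; batch path uses 50 fixed bisection
  iterations (resolution ~2e−15); scalar and batch endpoints agree to 1e−7.
* RMLE discriminants are clipped at zero only within 1e−9; worse violations
  raise. Probability estimates are clipped to [0,1] only against
  floating-point noise (<1e−12).
* Logistic-fit zero cells: +0.5 per complete-pair cell, fitting only.
* GEE: |α̂| ≤ 0.99; φ = 1 unless estimation is requested; separation raises.
* MI with m identical completed tables has zero between-imputation variance
  by construction; m ≥ 2 is required.
* All intervals are clipped to the parameter space [−1, 1] after
  construction, with a warning where clipping indicates a boundary issue.

## Known limitations

* The hybrid interval's within-patient correlation estimator is a
  documented choice (complete-pair phi); other software may use a different
  ρ̂, so hybrid results should be compared qualitatively.
* Wald-type intervals (MI, GEE delta) are anticonservative in small
  samples: exact enumeration at n = 20 (marginals 0.8, independent arms)
  puts true coverage of the nominal 90% Wald interval near 87%, and
  boundary type-I error of the Wald-type methods near 6% at n = 100 with
  high within-pair correlation. The score interval does not share this
  defect. The harness reports these operating characteristics as measured.
* GEE small-sample behavior under MAR depends materially on how degenerate
  (separated, near-unit working correlation) fits are handled; this package
  excludes and counts them rather than propagating divergent fits.
* No covariate-adjusted analyses, MNAR mechanisms, exact small-sample
  tests, or continuity corrections.
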