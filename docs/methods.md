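# Methods

## Model and assumptions

combatkit implements the empirical-Bayes location–scale model of batch
(center) effects. Each feature `g` measured on sample `j` of center `i`
is assumed to decompose as

    Y_ijg = α_g + X_j β_g + σ_g (γ_ig + δ_ig ε_ijg),  ε_ijg ~ N(0, 1)

with additive center effects `γ_ig ~ N(γ̄_i, τ̄²_i)` and multiplicative
effects `δ²_ig ~ InverseGamma(λ̄_i, θ̄_i)` a priori. The priors are
conjugate to the Normal likelihood of the standardized data, so the
conditional posterior means have the coupled closed form

    γ*_ig  = (n_i τ̄²_i γ̂_ig + δ²*_ig γ̄_i) / (n_i τ̄²_i + δ²*_ig)
    δ²*_ig = (θ̄_i + ½ Σ_j (Z_ijg − γ*_ig)²) / (n_i/2 + λ̄_i − 1)

solved by fixed-point iteration from the raw moments (relative-change
tolerance 1e−4, at most 200 iterations; non-convergence is recorded and
warned about, never raised). Hyperparameters come from the method of
moments across features: `γ̄, τ̄²` are the mean/variance of `γ̂_ig` over
`g`; matching the across-feature mean `M` and variance `V` of `δ̂²_ig`
to the Inverse-Gamma moments gives `λ̄ = M²/V + 2`, `θ̄ = M(λ̄ − 1)`.
When `V = 0` the scale prior is degenerate and the scale component falls
back to the raw per-batch variances for that batch.

Key identifiability fact: because standardization absorbs the
sample-size-weighted mean of the batch effects into `α̂_g` per feature,
only the *centered* component `γ_ig − Σ_i w_i γ_ig` (with `w_i = n_i/n`)
is estimable. Parameter-recovery checks therefore compare posterior
estimators against this identifiable component.

## Numerical conventions

- **Variance denominators.** The per-batch variance `δ̂²_ig` of the
  standardized data uses denominator `n_i`, matching the conjugate
  posterior's data term. The pooled residual SD `σ̂_g` likewise uses
  denominator `n` (population convention), and the per-batch per-feature
  SDs stored for reference-batch rescaling use `n_i`. Using one
  convention throughout makes the no-op adjustment (`γ* = 0, δ²* = 1`)
  invert standardization exactly and makes a single-center fit with
  shrinkage disabled an exact identity — properties the test suite
  asserts at 1e−10.
- **Standardization.** All variants standardize with the pooled
  `α̂_g, σ̂_g` (OLS with batch-mean terms plus covariates; the weighted
  grand mean of batch means plays the intercept role). Reference-center
  moments enter only at the adjustment step of the M variants.
- **Non-parametric posterior.** Realized as a leave-one-out
  likelihood-weighted average: for feature `g` in batch `i`, every other
  feature contributes a candidate pair `(γ̂_ig', (n/(n−1)) δ̂²_ig')`
  weighted by the Normal likelihood of feature `g`'s standardized data
  at that candidate. Weights are computed in log-space with
  max-subtraction, so arbitrarily extreme data cannot underflow to NaN;
  a fully degenerate weight row falls back to the feature's own raw
  moments with a warning.
- **Shrinkage-off mode** (`eb="none"`) substitutes the raw per-batch
  moments for the posteriors. It equals the closed-form per-batch
  location–scale alignment `((y − batch mean)/batch SD)·σ̂ + α̂` and is
  used as an independent oracle in the tests.
- **Zero-variance features** are rejected at fit time with the offending
  names (the CLI's `--drop-constant` removes them instead, with a log
  record). Missing values are rejected everywhere; imputation is out of
  scope. Batches need ≥ 2 samples (hard error); batches under 5 samples
  trigger a stability warning.

## Bootstrap variants

B-ComBat and BM-ComBat resample samples with replacement *within each
batch* (stratified case resampling, batch sizes preserved), rerun the
entire estimation chain per replicate, and average every estimator —
`α̂, σ̂, β̂`, the per-batch moments for reference rescaling, and the
posteriors `γ*, δ²*` (the variance parameter is averaged, not its square
root) — by arithmetic Monte-Carlo mean over replicates. The original,
non-resampled data is then adjusted with the averaged estimators. The
default is 100 replicates; everything is deterministic given the seed,
which is recorded in the fitted model. A replicate whose resample
produces a zero-variance feature is redrawn (up to 10 times) and then
skipped with a warning; the effective replicate count is stored.

The bootstrap mean of the shrunk estimator carries a small O(1/n)
resampling bias relative to the plain estimator, so convergence is
monitored against the replicate spread (`SD/√B`) between independent
bootstrap runs rather than against the plain fit.

## Transfer mode

A fitted model persists `(α̂, σ̂, β̂)`, the posterior estimators of
every registered batch, the covariate schema, and (for M variants) the
reference-center moments, as versioned JSON with full float precision.
`transform_new` standardizes incoming data with the *stored* global
estimates — nothing is re-estimated — and applies the stored estimators
of each sample's batch. This is the only reading under which the
transfer applied to the training data reproduces the fit-time output
(asserted to < 1e−8 for all variants and EB modes), and it works for a
single new sample. For bootstrap models the stored estimators are the
replicate-averaged ones; no re-bootstrap happens at transfer time.
Samples from a center absent at fit time are rejected by name: no
estimators exist for them, and few-shot adaptation to new centers is out
of scope.

## Synthetic data generator

The generator draws data from the model above, which is exactly the
setting the estimator assumes: per-feature base means and scales from
uniform ranges (defaults 5–50 and 0.5–3, echoing the heterogeneous units
of radiomic feature panels), center effects per batch either from the
Normal/Inverse-Gamma priors, from uniform ranges, or fixed, optional
Gaussian covariates with linear effects, and an optional binary outcome.
The default cohort is three centers of 117/44/28 samples (a four-scanner
layout 117/44/5/23 with one very small group is provided too), each with
its own default effect prior strong enough that most features differ
significantly between centers before harmonization — the regime
multi-center imaging cohorts actually show. The default outcome rate is
34% of events.

The outcome is linked by a logistic model to the *noise component* `ε`
of a random subset of informative features, with the intercept solved by
bisection to hit the requested event fraction. Tying the outcome to `ε`
rather than to `Y` makes it independent of the center effects by
construction, so harmonization can only help, never destroy, the signal
— the property the classifier-parity check relies on.

What the generator does **not** emulate: correlated feature blocks
(radiomic features are strongly inter-correlated; here features are
independent given the batch), non-Gaussian marginals, and center effects
that interact with the biology. Passing tests therefore demonstrate
correctness of the estimation and transfer machinery under the model's
own assumptions, not robustness to their violation.

Hold-out splitting is stratified by batch, and within batch by outcome
when one is present, preserving each stratum's event fraction to within
one sample; a designated hold-out batch can be routed entirely to the
test side to emulate a "new center" design.

## Statistical diagnostics

Per-feature one-way ANOVA across batch labels (scipy), with the share of
features significant at a stated α as the headline number; two-sample
Kolmogorov–Smirnov with asymptotic p-values; per-feature coefficient of
variation `100·SD/|mean|` with zero-mean features excluded by name and
the aggregate reported as the sum over retained features (the
per-feature vector is always returned so any other aggregation can be
recomputed); top-2 PCA on centered, unit-scaled features (correlation
PCA — the features have heterogeneous units) with a fixed sign
convention; Welch's t-test; and binary-classifier metrics where AUC is
the rank-based (Mann–Whitney) statistic with tie mid-ranks, balanced
accuracy is the mean of sensitivity and specificity at a stated
threshold, and Matthews correlation is defined as 0 when a
confusion-matrix margin vanishes. The metric implementations are
scikit-learn's; the test suite checks them against direct evaluation of
the defining formulas.

## Problem sizes and check design

The self-checks run on synthetic cohorts of 100–600 samples and 50–500
features — large enough for the asymptotic statistics to apply, small
enough to rerun constantly. Two design points deserve note:

- **Held-out transfer and ANOVA.** Estimators transferred from a 70%
  training split carry estimation noise of order `δ/√n_train` per
  feature, which inflates the between-batch variance of held-out samples
  by a factor ≈ `1 + w² n_test/n_train` (with `w` the shrinkage
  retention). When center effects are *systematic* — one shift and scale
  per center, the protocol-driven regime — shrinkage pools this noise
  away across features and the residual ANOVA rate stays near the
  nominal α; with fully idiosyncratic per-feature effects the EB prior
  has nothing to pool and the residual rate rises to ~3–5% at a 30%
  hold-out regardless of cohort size. The hold-out checks therefore use
  systematic center effects and report the rate averaged over many
  replicate experiments; the idiosyncratic regime is a genuine
  limitation of transfer harmonization, not of this implementation.
- **Null calibration bands** (ANOVA fraction ≈ α, AUC of uninformative
  scores ≈ 0.5) are asserted on averages over seeded replicates, sized
  so the Monte-Carlo standard error is well inside the band.

## Known limitations

- New centers cannot be harmonized; the model errors out by design.
- The parametric mode assumes approximate normality of standardized
  features; heavy-tailed features are better served by the
  non-parametric mode at ~G² cost per batch.
- COV aggregation (sum of per-feature percent COV) is one of several
  defensible conventions; the per-feature vector is exposed for any
  other.
- Bootstrap averaging stabilizes but slightly biases the estimators
  (O(1/n)); confidence intervals for harmonized values are not provided.
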