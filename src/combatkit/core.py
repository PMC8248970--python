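"""Location–scale harmonization of multi-center feature tables.

The model: a feature value from sample j of center i decomposes as

    Y_ijg = alpha_g + X_j beta_g + sigma_g * (gamma_ig + delta_ig eps_ijg)

where gamma_ig and delta²_ig are additive and multiplicative center
effects on the standardized scale and eps is unit Gaussian noise.
Harmonization estimates the center effects per feature, stabilizes them
by empirical-Bayes shrinkage toward batch-level priors
(gamma ~ Normal, delta² ~ Inverse-Gamma, hyperparameters fitted by the
method of moments), and removes them:

  1. standardize each feature with pooled OLS estimates of mean, scale
     and covariate effects;
  2. estimate per-batch moments of the standardized data and shrink them
     to their conditional posterior means (parametric conjugate form, or
     a non-parametric likelihood-weighted average across features);
  3. rescale either to the pooled mean/scale (standard variant) or to the
     moments of a chosen reference batch (M variant, which keeps
     physically meaningful units such as SUV or volume).

The fit is fully deterministic; the bootstrap-averaged variants live in
:mod:`combatkit.bootstrap`.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import (
    BatchEstimates,
    BatchVector,
    CovariateMatrix,
    FeatureMatrix,
    GlobalEstimates,
    Hyperparameters,
    PosteriorEstimates,
    StandardizedMatrix,
)
from .errors import BatchTooSmallError, SchemaError, ZeroVarianceError
from .model import HarmonizationModel

__all__ = [
    "build_design",
    "estimate_global",
    "standardize",
    "estimate_batch_effects",
    "estimate_hyperparameters",
    "eb_posterior_parametric",
    "eb_posterior_nonparametric",
    "shrinkage_off_posterior",
    "adjust_standard",
    "adjust_mcombat",
    "fit_transform",
]

SMALL_BATCH_WARN = 5  # the EB machinery is documented as robust down to ~5/batch


def build_design(raw_covariates: pd.DataFrame | None,
                 encoding_spec: dict | None = None) -> CovariateMatrix:
    """Encode raw per-sample covariates into a design block.

    Categorical columns (object/category dtype, or declared
    ``"categorical"`` in ``encoding_spec``) are one-hot encoded with the
    first level dropped; numeric columns pass through.  No intercept
    column is added — the pooled mean plays that role.

    Raises on missing values and on columns that are constant after
    encoding (they would be confounded with the intercept).
    """
    if raw_covariates is None or raw_covariates.shape[1] == 0:
        n = 0 if raw_covariates is None else len(raw_covariates)
        return CovariateMatrix.empty(n)
    df = raw_covariates.copy()
    if df.isna().any().any():
        bad = list(df.columns[df.isna().any()])
        raise SchemaError("covariates contain missing values in: " + ", ".join(bad))
    encoding_spec = encoding_spec or {}
    blocks, names = [], []
    for col in df.columns:
        kind = encoding_spec.get(col)
        if kind is None:
            kind = ("categorical"
                    if df[col].dtype == object
                    or isinstance(df[col].dtype, pd.CategoricalDtype)
                    else "numeric")
        if kind == "categorical":
            levels = list(pd.unique(df[col].astype(str)))
            if len(levels) < 2:
                raise SchemaError(f"covariate column {col!r} is constant after encoding")
            for lev in levels[1:]:
                blocks.append((df[col].astype(str) == lev).to_numpy(float))
                names.append(f"{col}[{lev}]")
        elif kind == "numeric":
            vals = pd.to_numeric(df[col], errors="raise").to_numpy(float)
            if np.ptp(vals) == 0:
                raise SchemaError(f"covariate column {col!r} is constant after encoding")
            blocks.append(vals)
            names.append(str(col))
        else:
            raise SchemaError(f"unknown encoding {kind!r} for column {col!r}")
    return CovariateMatrix(np.column_stack(blocks), names)


def _check_alignment(Y: FeatureMatrix, batches: BatchVector,
                     X: CovariateMatrix | None) -> CovariateMatrix:
    if batches.n_samples != Y.n_samples:
        raise SchemaError("batch labels do not align with the feature matrix")
    if X is None:
        X = CovariateMatrix.empty(Y.n_samples)
    if X.n_covariates and X.design.shape[0] != Y.n_samples:
        raise SchemaError("covariate rows do not align with the feature matrix")
    return X


def estimate_global(Y: FeatureMatrix, batches: BatchVector,
                    X: CovariateMatrix | None = None) -> GlobalEstimates:
    """Pooled mean/scale and covariate coefficients, by feature-wise OLS.

    One least-squares fit per feature with batch-mean terms plus the
    covariate block.  The pooled mean ``alpha`` is the sample-size
    weighted average of the batch means; ``sigma`` is the population
    residual SD (denominator n, matching the per-batch variance
    convention so that a no-op adjustment is an exact identity);
    per-batch mean/SD of the covariate-residualized data are kept for
    reference-batch rescaling.
    """
    X = _check_alignment(Y, batches, X)
    n, g = Y.values.shape
    counts = batches.counts()
    empty = [b for b, c in zip(batches.registry, counts) if c == 0]
    if empty:
        raise SchemaError("registry batches without samples: " + ", ".join(empty))

    rows = batches.row_index()
    onehot = np.zeros((n, batches.n_batches))
    onehot[np.arange(n), rows] = 1.0
    design = np.hstack([onehot, X.design]) if X.n_covariates else onehot

    coef, _, rank, _ = np.linalg.lstsq(design, Y.values, rcond=None)
    if rank < design.shape[1]:
        raise SchemaError("design matrix is rank deficient (collinear covariates?)")
    if n - rank <= 0:
        raise SchemaError("no residual degrees of freedom (n too small)")

    batch_means = coef[: batches.n_batches]          # (B, G)
    beta = coef[batches.n_batches:]                  # (p, G)
    alpha = (counts / n) @ batch_means               # weighted grand mean

    resid = Y.values - design @ coef
    sigma2 = np.einsum("ij,ij->j", resid, resid) / n
    scale = np.maximum(1.0, np.mean(Y.values ** 2, axis=0))
    zero = sigma2 <= 1e-24 * scale
    if np.any(zero):
        raise ZeroVarianceError([Y.feature_names[i] for i in np.flatnonzero(zero)])

    resid_cov = Y.values - (X.design @ beta if X.n_covariates else 0.0)
    pb_alpha = np.empty((batches.n_batches, g))
    pb_sigma = np.empty((batches.n_batches, g))
    for i, b in enumerate(batches.registry):
        block = resid_cov[batches.indices(b)]
        pb_alpha[i] = block.mean(axis=0)
        pb_sigma[i] = block.std(axis=0)  # population SD; matches delta²-hat

    return GlobalEstimates(
        alpha=alpha, sigma=np.sqrt(sigma2), beta=beta,
        per_batch_alpha=pb_alpha, per_batch_sigma=pb_sigma,
        feature_names=list(Y.feature_names),
        covariate_names=list(X.column_names),
        batch_registry=list(batches.registry),
    )


def _xb(globals_: GlobalEstimates, X: CovariateMatrix | None, n: int):
    if X is None or X.n_covariates == 0:
        if globals_.covariate_names:
            raise SchemaError("fitted with covariates but none supplied")
        return 0.0
    if list(X.column_names) != list(globals_.covariate_names):
        raise SchemaError("covariate columns do not match the fitted estimates")
    return X.design @ globals_.beta


def standardize(Y: FeatureMatrix, globals_: GlobalEstimates,
                X: CovariateMatrix | None = None) -> StandardizedMatrix:
    """Z = (Y - alpha - X beta) / sigma, elementwise per feature."""
    if list(Y.feature_names) != list(globals_.feature_names):
        raise SchemaError("feature names do not match the fitted global estimates")
    z = (Y.values - globals_.alpha - _xb(globals_, X, Y.n_samples)) / globals_.sigma
    return StandardizedMatrix(z, list(Y.sample_ids), list(Y.feature_names))


def estimate_batch_effects(Z: StandardizedMatrix,
                           batches: BatchVector) -> BatchEstimates:
    """Per-batch mean and variance (denominator n_i) of the standardized data."""
    if batches.n_samples != Z.values.shape[0]:
        raise SchemaError("batch labels do not align with the standardized matrix")
    b, g = batches.n_batches, Z.values.shape[1]
    gamma_hat = np.empty((b, g))
    delta2_hat = np.empty((b, g))
    counts = np.empty(b, dtype=int)
    for i, batch in enumerate(batches.registry):
        idx = batches.indices(batch)
        counts[i] = idx.size
        if idx.size < 2:
            raise BatchTooSmallError(batch)
        if idx.size < SMALL_BATCH_WARN:
            warnings.warn(
                f"batch {batch!r} has only {idx.size} samples; "
                "center-effect estimates will be unstable", stacklevel=2)
        block = Z.values[idx]
        gamma_hat[i] = block.mean(axis=0)
        delta2_hat[i] = block.var(axis=0)
    return BatchEstimates(gamma_hat, delta2_hat, counts)


def estimate_hyperparameters(est: BatchEstimates) -> Hyperparameters:
    """Method-of-moments empirical priors across features, per batch.

    Normal prior on gamma: mean and variance of gamma-hat across features.
    Inverse-Gamma prior on delta²: matching the across-feature mean M and
    variance V of delta²-hat gives lambda = M²/V + 2, theta = M(lambda-1).
    If V = 0 the prior is degenerate and scale shrinkage is disabled for
    that batch (the posterior keeps the raw per-batch variance).
    """
    if est.gamma_hat.shape[1] < 2:
        raise SchemaError("hyperparameter estimation needs at least 2 features")
    gamma_bar = est.gamma_hat.mean(axis=1)
    tau2_bar = est.gamma_hat.var(axis=1, ddof=1)
    m = est.delta2_hat.mean(axis=1)
    v = est.delta2_hat.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lambda_bar = np.where(v > 0, m ** 2 / v + 2.0, np.inf)
    theta_bar = np.where(v > 0, m * (lambda_bar - 1.0), m)
    scale_shrink = v > 0
    return Hyperparameters(gamma_bar, tau2_bar, lambda_bar, theta_bar, scale_shrink)


def _batch_sums(Z: StandardizedMatrix, batches: BatchVector,
                est: BatchEstimates):
    """Per-batch (n, mean, centered sum of squares) of Z, from the moments."""
    n = est.n_per_batch.astype(float)
    s = est.delta2_hat * n[:, None]  # sum_j (Z - mean)²
    return n, est.gamma_hat, s


def eb_posterior_parametric(Z: StandardizedMatrix, batches: BatchVector,
                            est: BatchEstimates, hyper: Hyperparameters,
                            tol: float = 1e-4,
                            max_iter: int = 200) -> PosteriorEstimates:
    """Conjugate conditional posterior means by fixed-point iteration.

    Solves, per batch i and feature g,

        gamma* = (n tau² gamma-hat + delta²* gamma-bar) / (n tau² + delta²*)
        delta²* = (theta-bar + ½ Σ_j (Z_jg - gamma*)²) / (n/2 + lambda-bar - 1)

    initialized at the raw moments.  ``tau2_bar = inf`` turns location
    shrinkage off (gamma* = gamma-hat); batches flagged ``scale_shrink =
    False`` keep delta²* = delta²-hat.  Non-convergence yields a warning,
    not an exception, with ``converged`` flags in the result.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    nb, g = est.gamma_hat.shape
    n, mean_z, ss = _batch_sums(Z, batches, est)
    gamma_star = np.empty((nb, g))
    delta2_star = np.empty((nb, g))
    converged = np.zeros(nb, dtype=bool)
    iterations = np.zeros(nb, dtype=int)

    for i in range(nb):
        g_hat, d_hat = est.gamma_hat[i], est.delta2_hat[i]
        t2, g_bar = hyper.tau2_bar[i], hyper.gamma_bar[i]
        lam, th = hyper.lambda_bar[i], hyper.theta_bar[i]
        ni = n[i]

        if not hyper.scale_shrink[i]:
            # degenerate Inverse-Gamma prior: keep the raw variances
            d = d_hat.copy()
            gamma_star[i] = _post_gamma(g_hat, d, ni, t2, g_bar)
            delta2_star[i] = d
            converged[i], iterations[i] = True, 1
            continue

        gcur, dcur = g_hat.copy(), d_hat.copy()
        for it in range(1, max_iter + 1):
            gnew = _post_gamma(g_hat, dcur, ni, t2, g_bar)
            sum2 = ss[i] + ni * (mean_z[i] - gnew) ** 2
            dnew = (th + 0.5 * sum2) / (ni / 2.0 + lam - 1.0)
            change = max(
                np.max(np.abs(gnew - gcur) / np.maximum(np.abs(gcur), 1e-6)),
                np.max(np.abs(dnew - dcur) / np.maximum(np.abs(dcur), 1e-6)),
            )
            gcur, dcur = gnew, dnew
            if change < tol:
                converged[i] = True
                break
        iterations[i] = it
        if not converged[i]:
            warnings.warn(
                f"EB posterior for batch {batches.registry[i]!r} did not "
                f"converge in {max_iter} iterations", stacklevel=2)
        gamma_star[i], delta2_star[i] = gcur, dcur

    if np.any(delta2_star <= 0):
        raise ZeroVarianceError(
            [Z.feature_names[j] for j in
             np.unique(np.nonzero(delta2_star <= 0)[1])])
    return PosteriorEstimates(gamma_star, delta2_star, converged, iterations)


def _post_gamma(g_hat, d, n, t2, g_bar):
    if np.isinf(t2):
        return g_hat.copy()
    return (n * t2 * g_hat + d * g_bar) / (n * t2 + d)


def eb_posterior_nonparametric(Z: StandardizedMatrix, batches: BatchVector,
                               est: BatchEstimates) -> PosteriorEstimates:
    """Non-parametric posterior: likelihood-weighted average across features.

    For batch i and feature g, every *other* feature g' contributes a
    candidate pair (gamma-hat_ig', n/(n-1)-adjusted delta²-hat_ig')
    weighted by the Normal likelihood of feature g's standardized data in
    batch i evaluated at that candidate.  Weights are computed in
    log-space with max-subtraction, so extreme data cannot underflow to
    NaN; a row whose weights are all degenerate falls back to the
    feature's own raw moments with a warning.
    """
    nb, g = est.gamma_hat.shape
    if g < 2:
        raise SchemaError("non-parametric EB needs at least 2 features")
    n, mean_z, ss = _batch_sums(Z, batches, est)
    gamma_star = np.empty((nb, g))
    delta2_star = np.empty((nb, g))

    for i in range(nb):
        ni = n[i]
        g_cand = est.gamma_hat[i]
        d_cand = est.delta2_hat[i] * ni / (ni - 1.0)
        # sum_j (Z_jg - g')² = SS_g + n (mean_g - g')², for all (g, g') pairs
        a = ss[i][:, None] + ni * (mean_z[i][:, None] - g_cand[None, :]) ** 2
        logw = (-0.5 * ni * np.log(2.0 * np.pi * d_cand)[None, :]
                - a / (2.0 * d_cand[None, :]))
        np.fill_diagonal(logw, -np.inf)
        logw -= logw.max(axis=1, keepdims=True)
        w = np.exp(logw)
        wsum = w.sum(axis=1)
        bad = ~np.isfinite(wsum) | (wsum <= 0)
        wsum = np.where(bad, 1.0, wsum)
        gamma_star[i] = w @ g_cand / wsum
        delta2_star[i] = w @ d_cand / wsum
        if np.any(bad):
            warnings.warn(
                f"non-parametric weights degenerate for {int(bad.sum())} "
                f"feature(s) in batch {batches.registry[i]!r}; "
                "falling back to raw moments", stacklevel=2)
            gamma_star[i][bad] = est.gamma_hat[i][bad]
            delta2_star[i][bad] = est.delta2_hat[i][bad]

    if np.any(delta2_star <= 0):
        raise ZeroVarianceError(
            [Z.feature_names[j] for j in
             np.unique(np.nonzero(delta2_star <= 0)[1])])
    return PosteriorEstimates(gamma_star, delta2_star,
                              np.ones(nb, dtype=bool), np.ones(nb, dtype=int))


def shrinkage_off_posterior(est: BatchEstimates) -> PosteriorEstimates:
    """Identity 'posterior': the raw per-batch moments, no shrinkage."""
    if np.any(est.delta2_hat <= 0):
        raise ZeroVarianceError(
            [str(j) for j in np.unique(np.nonzero(est.delta2_hat <= 0)[1])])
    nb = est.gamma_hat.shape[0]
    return PosteriorEstimates(est.gamma_hat.copy(), est.delta2_hat.copy(),
                              np.ones(nb, dtype=bool), np.zeros(nb, dtype=int))


def _adjust(Z, post, batches, out_scale, out_loc, xb):
    rows = batches.row_index()
    g_star = post.gamma_star[rows]
    d_star = np.sqrt(post.delta2_star[rows])
    return (out_scale / d_star) * (Z.values - g_star) + out_loc + xb


def adjust_standard(Z: StandardizedMatrix, post: PosteriorEstimates,
                    globals_: GlobalEstimates, X: CovariateMatrix | None,
                    batches: BatchVector) -> FeatureMatrix:
    """Remove center effects and restore the pooled mean/scale.

    Y* = (sigma / delta*) (Z - gamma*) + alpha + X beta; inverts
    standardization exactly when gamma* = 0 and delta²* = 1.
    """
    xb = _xb(globals_, X, Z.values.shape[0])
    vals = _adjust(Z, post, batches, globals_.sigma, globals_.alpha, xb)
    return FeatureMatrix(vals, list(Z.sample_ids), list(Z.feature_names))


def adjust_mcombat(Z: StandardizedMatrix, post: PosteriorEstimates,
                   globals_: GlobalEstimates, X: CovariateMatrix | None,
                   batches: BatchVector, reference_batch) -> FeatureMatrix:
    """Remove center effects and restore the reference batch's moments.

    As :func:`adjust_standard` but rescaling with the reference batch's
    per-feature mean and SD, so harmonized values stay on that center's
    physical scale.
    """
    reference_batch = str(reference_batch)
    if reference_batch not in globals_.batch_registry:
        from .errors import UnknownBatchError
        raise UnknownBatchError([reference_batch])
    r = globals_.batch_registry.index(reference_batch)
    xb = _xb(globals_, X, Z.values.shape[0])
    vals = _adjust(Z, post, batches, globals_.per_batch_sigma[r],
                   globals_.per_batch_alpha[r], xb)
    return FeatureMatrix(vals, list(Z.sample_ids), list(Z.feature_names))


def _fit_estimates(Y: FeatureMatrix, batches: BatchVector,
                   X: CovariateMatrix | None, eb: str,
                   tol: float, max_iter: int):
    """Run the estimation chain; returns (globals, batch est, posterior)."""
    globals_ = estimate_global(Y, batches, X)
    z = standardize(Y, globals_, X)
    est = estimate_batch_effects(z, batches)
    if eb == "parametric":
        hyper = estimate_hyperparameters(est)
        post = eb_posterior_parametric(z, batches, est, hyper, tol, max_iter)
    elif eb == "nonparametric":
        post = eb_posterior_nonparametric(z, batches, est)
    elif eb == "none":
        post = shrinkage_off_posterior(est)
    else:
        raise SchemaError(f"unknown EB mode {eb!r}")
    return globals_, z, est, post


def fit_transform(Y: FeatureMatrix, batches: BatchVector,
                  X: CovariateMatrix | None = None, *,
                  variant: str = "combat", eb: str = "parametric",
                  reference_batch=None, tol: float = 1e-4,
                  max_iter: int = 200, n_replicates: int = 100,
                  seed: int | None = None):
    """Fit a harmonization transform and return (model, adjusted data).

    ``variant`` is one of ``combat``, ``m-combat``, ``b-combat``,
    ``bm-combat``; the M variants require ``reference_batch`` and the B
    variants a ``seed`` (plus ``n_replicates``, default 100).  ``eb``
    selects the shrinkage mode: ``parametric``, ``nonparametric`` or
    ``none``.
    """
    if variant in ("b-combat", "bm-combat"):
        from .bootstrap import fit_transform_bootstrap
        return fit_transform_bootstrap(
            Y, batches, X, variant=variant, eb=eb,
            reference_batch=reference_batch, n_replicates=n_replicates,
            seed=0 if seed is None else seed, tol=tol, max_iter=max_iter)
    if variant not in ("combat", "m-combat"):
        raise SchemaError(f"unknown variant {variant!r}")
    if variant == "m-combat" and reference_batch is None:
        raise SchemaError("m-combat requires a reference batch")
    if variant == "combat" and reference_batch is not None:
        raise SchemaError("reference_batch is only valid for the M variants")

    X = _check_alignment(Y, batches, X)
    globals_, z, est, post = _fit_estimates(Y, batches, X, eb, tol, max_iter)

    if variant == "m-combat":
        adjusted = adjust_mcombat(z, post, globals_, X, batches, reference_batch)
        r = globals_.batch_registry.index(str(reference_batch))
        ref_alpha, ref_sigma = globals_.per_batch_alpha[r], globals_.per_batch_sigma[r]
        ref_batch = str(reference_batch)
    else:
        adjusted = adjust_standard(z, post, globals_, X, batches)
        ref_alpha = ref_sigma = ref_batch = None

    from . import __version__
    model = HarmonizationModel(
        variant=variant, eb=eb, batches=list(batches.registry),
        feature_names=list(Y.feature_names),
        covariate_names=list(globals_.covariate_names),
        alpha=globals_.alpha, sigma=globals_.sigma, beta=globals_.beta,
        gamma_star=post.gamma_star, delta2_star=post.delta2_star,
        ref_batch=ref_batch, ref_alpha=ref_alpha, ref_sigma=ref_sigma,
        bootstrap=None,
        meta={"tool": "combatkit", "version": __version__},
    )
    return model, adjusted
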