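"""Bootstrap-averaged harmonization (B-ComBat and BM-ComBat).

The estimation stage of the location–scale model is resampled: samples
are drawn with replacement *within each batch* (stratified, preserving
the batch sizes), the full estimation chain is rerun on each replicate,
and every estimator — pooled mean/scale, covariate coefficients, and the
posterior center-effect estimators — is averaged over replicates by
Monte-Carlo mean.  The original (non-resampled) data is then adjusted
with the averaged estimators, using either the grand-mean (B-ComBat) or
the reference-batch (BM-ComBat) rescaling.

Averaging is done on the parameters themselves (delta²*, not delta*).
Everything is deterministic given the seed.
"""

from __future__ import annotations

import warnings

import numpy as np

from .containers import (
    AveragedEstimates,
    BatchVector,
    CovariateMatrix,
    FeatureMatrix,
    GlobalEstimates,
    PosteriorEstimates,
    StandardizedMatrix,
)
from .core import (
    _check_alignment,
    _fit_estimates,
    adjust_mcombat,
    adjust_standard,
)
from .errors import SchemaError, ZeroVarianceError
from .model import HarmonizationModel

__all__ = ["bootstrap_fit", "fit_transform_bootstrap"]

MAX_RETRIES = 10


def _stratified_indices(rng: np.random.Generator,
                        batches: BatchVector) -> np.ndarray:
    """Within-batch resample with replacement, batch sizes preserved."""
    parts = []
    for b in batches.registry:
        idx = batches.indices(b)
        parts.append(idx[rng.integers(0, idx.size, idx.size)])
    return np.concatenate(parts)


def bootstrap_fit(Y: FeatureMatrix, batches: BatchVector,
                  X: CovariateMatrix | None = None, *,
                  eb: str = "parametric", n_replicates: int = 100,
                  seed: int = 0, tol: float = 1e-4, max_iter: int = 200,
                  index_sampler=None) -> AveragedEstimates:
    """Resample the estimation stage and average the estimators.

    ``index_sampler(rng, batches) -> indices`` may override the default
    stratified-with-replacement scheme (useful for testing).  A replicate
    whose resample produces a zero-variance feature is redrawn up to 10
    times, then skipped with a warning; ``replicate_count_used`` records
    the effective number of replicates.
    """
    if n_replicates < 1:
        raise SchemaError("n_replicates must be >= 1")
    X = _check_alignment(Y, batches, X)
    rng = np.random.default_rng(seed)
    sampler = index_sampler or _stratified_indices

    acc: dict[str, list[np.ndarray]] = {k: [] for k in (
        "alpha", "sigma", "beta", "pb_alpha", "pb_sigma", "gamma", "delta2")}
    used = 0
    for _ in range(n_replicates):
        for attempt in range(MAX_RETRIES + 1):
            idx = np.asarray(sampler(rng, batches))
            yb = FeatureMatrix(Y.values[idx],
                               [f"r{j}" for j in range(idx.size)],
                               list(Y.feature_names))
            bb = BatchVector.from_labels(batches.labels[idx],
                                         registry=batches.registry)
            xb = (CovariateMatrix(X.design[idx], list(X.column_names))
                  if X.n_covariates else None)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    g_, _, _, post = _fit_estimates(yb, bb, xb, eb, tol, max_iter)
                break
            except ZeroVarianceError:
                if attempt == MAX_RETRIES:
                    warnings.warn(
                        "bootstrap replicate skipped: zero-variance feature "
                        f"after {MAX_RETRIES} redraws", stacklevel=2)
                    g_ = None
        if g_ is None:
            continue
        acc["alpha"].append(g_.alpha)
        acc["sigma"].append(g_.sigma)
        acc["beta"].append(g_.beta)
        acc["pb_alpha"].append(g_.per_batch_alpha)
        acc["pb_sigma"].append(g_.per_batch_sigma)
        acc["gamma"].append(post.gamma_star)
        acc["delta2"].append(post.delta2_star)
        used += 1

    if used == 0:
        raise ZeroVarianceError(Y.feature_names)
    gamma = np.stack(acc["gamma"])
    delta2 = np.stack(acc["delta2"])
    ddof = 1 if used > 1 else 0
    return AveragedEstimates(
        alpha_bar=np.mean(acc["alpha"], axis=0),
        sigma_bar=np.mean(acc["sigma"], axis=0),
        beta_bar=np.mean(acc["beta"], axis=0),
        per_batch_alpha_bar=np.mean(acc["pb_alpha"], axis=0),
        per_batch_sigma_bar=np.mean(acc["pb_sigma"], axis=0),
        gamma_star_bar=gamma.mean(axis=0),
        delta2_star_bar=delta2.mean(axis=0),
        gamma_star_sd=gamma.std(axis=0, ddof=ddof),
        delta2_star_sd=delta2.std(axis=0, ddof=ddof),
        replicate_count_used=used,
    )


def fit_transform_bootstrap(Y: FeatureMatrix, batches: BatchVector,
                            X: CovariateMatrix | None = None, *,
                            variant: str = "b-combat",
                            eb: str = "parametric",
                            reference_batch=None,
                            n_replicates: int = 100, seed: int = 0,
                            tol: float = 1e-4, max_iter: int = 200,
                            index_sampler=None):
    """Fit B-ComBat / BM-ComBat and return (model, adjusted data).

    The original data is standardized with the replicate-averaged global
    estimates and adjusted with the replicate-averaged posterior
    estimators; BM-ComBat rescales to the averaged reference-batch
    moments.
    """
    if variant not in ("b-combat", "bm-combat"):
        raise SchemaError(f"unknown bootstrap variant {variant!r}")
    if variant == "bm-combat" and reference_batch is None:
        raise SchemaError("bm-combat requires a reference batch")
    if variant == "b-combat" and reference_batch is not None:
        raise SchemaError("reference_batch is only valid for the M variants")
    X = _check_alignment(Y, batches, X)

    avg = bootstrap_fit(Y, batches, X, eb=eb, n_replicates=n_replicates,
                        seed=seed, tol=tol, max_iter=max_iter,
                        index_sampler=index_sampler)

    globals_ = GlobalEstimates(
        alpha=avg.alpha_bar, sigma=avg.sigma_bar, beta=avg.beta_bar,
        per_batch_alpha=avg.per_batch_alpha_bar,
        per_batch_sigma=avg.per_batch_sigma_bar,
        feature_names=list(Y.feature_names),
        covariate_names=list(X.column_names),
        batch_registry=list(batches.registry),
    )
    z = StandardizedMatrix(
        (Y.values - globals_.alpha
         - (X.design @ globals_.beta if X.n_covariates else 0.0))
        / globals_.sigma,
        list(Y.sample_ids), list(Y.feature_names))
    nb = batches.n_batches
    post = PosteriorEstimates(avg.gamma_star_bar, avg.delta2_star_bar,
                              np.ones(nb, dtype=bool), np.ones(nb, dtype=int))

    if variant == "bm-combat":
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
        covariate_names=list(X.column_names),
        alpha=globals_.alpha, sigma=globals_.sigma, beta=globals_.beta,
        gamma_star=post.gamma_star, delta2_star=post.delta2_star,
        ref_batch=ref_batch, ref_alpha=ref_alpha, ref_sigma=ref_sigma,
        bootstrap={"n_replicates": n_replicates, "seed": seed,
                   "replicate_count_used": avg.replicate_count_used},
        meta={"tool": "combatkit", "version": __version__},
    )
    return model, adjusted
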