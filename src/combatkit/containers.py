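"""In-memory containers for feature tables and harmonization estimates.

The central object is a :class:`FeatureMatrix` — a samples × features
numeric table with sample and feature identifiers — accompanied by a
:class:`BatchVector` of per-sample center/batch labels and an optional
:class:`CovariateMatrix` of encoded non-batch covariates.  The remaining
dataclasses carry the intermediate quantities of the location–scale
harmonization model: pooled and per-batch moments, empirical-Bayes prior
hyperparameters, and the posterior center-effect estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = [
    "FeatureMatrix",
    "BatchVector",
    "CovariateMatrix",
    "StandardizedMatrix",
    "GlobalEstimates",
    "BatchEstimates",
    "Hyperparameters",
    "PosteriorEstimates",
    "BootstrapConfig",
    "AveragedEstimates",
]


def _check_unique(names, kind: str) -> list[str]:
    names = [str(x) for x in names]
    if len(set(names)) != len(names):
        seen, dupes = set(), []
        for x in names:
            if x in seen:
                dupes.append(x)
            seen.add(x)
        raise SchemaError(f"duplicate {kind}: {', '.join(sorted(set(dupes)))}")
    return names


@dataclass
class FeatureMatrix:
    """Numeric feature table, samples as rows.

    Parameters
    ----------
    values : ndarray, shape (n_samples, n_features)
        Finite feature values.
    sample_ids : sequence of str
        Unique per-sample identifiers, one per row.
    feature_names : sequence of str
        Unique feature identifiers, one per column.
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_names: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise SchemaError("feature values must be a 2-D samples × features array")
        if not np.all(np.isfinite(self.values)):
            raise SchemaError("feature values contain non-finite entries")
        self.sample_ids = _check_unique(self.sample_ids, "sample ids")
        self.feature_names = _check_unique(self.feature_names, "feature names")
        n, g = self.values.shape
        if len(self.sample_ids) != n:
            raise SchemaError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.feature_names) != g:
            raise SchemaError(f"{len(self.feature_names)} feature names for {g} columns")
        if g < 1:
            raise SchemaError("at least one feature is required")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_names
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index.astype(str)),
                   list(df.columns.astype(str)))


@dataclass
class StandardizedMatrix:
    """Feature table on the standardized scale (pooled mean 0, pooled SD 1).

    Produced only by :func:`combatkit.core.standardize`; carries the same
    identifiers as its source :class:`FeatureMatrix`.
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_names: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise SchemaError("standardized values contain non-finite entries")


@dataclass
class BatchVector:
    """Per-sample batch (center/scanner) labels plus an ordered registry.

    The registry fixes the row order of every batches × features estimate
    array; by default it is the order of first appearance in ``labels``.
    """

    labels: np.ndarray
    registry: list[str]

    def __post_init__(self):
        self.labels = np.asarray([str(x) for x in np.asarray(self.labels).ravel()],
                                 dtype=object)
        self.registry = _check_unique(self.registry, "batch ids")
        known = set(self.registry)
        unknown = sorted({x for x in self.labels if x not in known})
        if unknown:
            raise SchemaError("labels outside the batch registry: " + ", ".join(unknown))

    @classmethod
    def from_labels(cls, labels, registry=None) -> "BatchVector":
        labels = [str(x) for x in np.asarray(labels).ravel()]
        if registry is None:
            registry = list(dict.fromkeys(labels))
        return cls(np.asarray(labels, dtype=object), list(registry))

    @property
    def n_samples(self) -> int:
        return self.labels.shape[0]

    @property
    def n_batches(self) -> int:
        return len(self.registry)

    def indices(self, batch) -> np.ndarray:
        """Row indices of the samples belonging to ``batch``."""
        return np.flatnonzero(self.labels == str(batch))

    def counts(self) -> np.ndarray:
        """Sample count per registry batch (may contain zeros)."""
        return np.array([self.indices(b).size for b in self.registry])

    def row_index(self) -> np.ndarray:
        """For each sample, the registry position of its batch."""
        pos = {b: i for i, b in enumerate(self.registry)}
        return np.array([pos[x] for x in self.labels], dtype=int)


@dataclass
class CovariateMatrix:
    """Encoded non-batch covariates (design block X, no intercept column)."""

    design: np.ndarray
    column_names: list[str]

    def __post_init__(self):
        self.design = np.asarray(self.design, dtype=float)
        if self.design.ndim != 2:
            raise SchemaError("covariate design must be 2-D")
        if self.design.size and not np.all(np.isfinite(self.design)):
            raise SchemaError("covariate design contains non-finite entries")
        self.column_names = _check_unique(self.column_names, "covariate columns")
        if len(self.column_names) != self.design.shape[1]:
            raise SchemaError("covariate names do not match design width")
        if self.design.shape[1] > 0:
            if np.linalg.matrix_rank(self.design) < self.design.shape[1]:
                raise SchemaError("covariate design is rank deficient")

    @classmethod
    def empty(cls, n_samples: int) -> "CovariateMatrix":
        return cls(np.empty((n_samples, 0)), [])

    @property
    def n_covariates(self) -> int:
        return self.design.shape[1]


@dataclass
class GlobalEstimates:
    """Pooled location–scale estimates from the standardization fit.

    ``alpha``/``sigma`` are the pooled per-feature mean and residual SD;
    ``beta`` the covariate coefficients (p × G).  ``per_batch_alpha`` /
    ``per_batch_sigma`` hold the per-batch per-feature mean and population
    SD of the covariate-residualized data, used by the reference-batch
    (M-type) adjustment.
    """

    alpha: np.ndarray          # (G,)
    sigma: np.ndarray          # (G,) strictly positive
    beta: np.ndarray           # (p, G)
    per_batch_alpha: np.ndarray  # (B, G)
    per_batch_sigma: np.ndarray  # (B, G)
    feature_names: list[str]
    covariate_names: list[str]
    batch_registry: list[str]


@dataclass
class BatchEstimates:
    """Per-batch moments of the standardized data (gamma-hat, delta²-hat)."""

    gamma_hat: np.ndarray    # (B, G)
    delta2_hat: np.ndarray   # (B, G) >= 0
    n_per_batch: np.ndarray  # (B,)


@dataclass
class Hyperparameters:
    """Empirical prior hyperparameters, one set per batch.

    gamma_bar/tau2_bar parameterize the Normal prior on the additive batch
    effect; lambda_bar/theta_bar the Inverse-Gamma prior on the
    multiplicative one.  ``scale_shrink`` flags batches where the
    Inverse-Gamma moment system was solvable; where it is False the scale
    component falls back to the raw per-batch variance (no shrinkage).
    """

    gamma_bar: np.ndarray   # (B,)
    tau2_bar: np.ndarray    # (B,) >= 0
    lambda_bar: np.ndarray  # (B,)
    theta_bar: np.ndarray   # (B,)
    scale_shrink: np.ndarray = field(default=None)  # (B,) bool

    def __post_init__(self):
        if self.scale_shrink is None:
            self.scale_shrink = np.ones(np.shape(self.gamma_bar), dtype=bool)


@dataclass
class PosteriorEstimates:
    """Conditional-posterior center-effect estimators (gamma*, delta²*)."""

    gamma_star: np.ndarray   # (B, G)
    delta2_star: np.ndarray  # (B, G) > 0
    converged: np.ndarray    # (B,) bool
    iterations: np.ndarray   # (B,) int


@dataclass
class BootstrapConfig:
    """Configuration of the bootstrap estimation stage."""

    n_replicates: int = 100
    seed: int = 0
    variant: str = "combat"
    reference_batch: str | None = None

    def __post_init__(self):
        if self.n_replicates < 1:
            raise SchemaError("bootstrap n_replicates must be >= 1")


@dataclass
class AveragedEstimates:
    """Monte-Carlo means of the estimators over bootstrap replicates."""

    alpha_bar: np.ndarray
    sigma_bar: np.ndarray
    beta_bar: np.ndarray
    per_batch_alpha_bar: np.ndarray
    per_batch_sigma_bar: np.ndarray
    gamma_star_bar: np.ndarray
    delta2_star_bar: np.ndarray
    gamma_star_sd: np.ndarray    # replicate spread, for MC-error monitoring
    delta2_star_sd: np.ndarray
    replicate_count_used: int
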