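"""Persisted harmonization transform and its application to new samples.

A fitted model stores everything needed to harmonize additional samples
from already-registered centers without refitting: the pooled location
and scale estimates, covariate coefficients, and the per-batch posterior
center-effect estimators (gamma*, delta²*).  ``transform_new`` standardizes
new data with the *stored* global estimates and applies the stored
per-batch estimators, so applying a model back to its own training data
reproduces the fit-time harmonized output exactly.

Data from a center absent at fit time cannot be harmonized — no estimators
exist for it — and raises :class:`~combatkit.errors.UnknownBatchError`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .containers import BatchVector, CovariateMatrix, FeatureMatrix
from .errors import FeatureMismatchError, SchemaError, UnknownBatchError

SCHEMA_VERSION = 1

VARIANTS = ("combat", "m-combat", "b-combat", "bm-combat")
EB_MODES = ("parametric", "nonparametric", "none")

__all__ = ["HarmonizationModel", "save_model", "load_model", "transform_new",
           "SCHEMA_VERSION", "VARIANTS", "EB_MODES"]


@dataclass
class HarmonizationModel:
    """A fitted, persistable center-effect harmonization transform.

    Attributes
    ----------
    variant : one of ``combat``, ``m-combat``, ``b-combat``, ``bm-combat``
    eb : empirical-Bayes mode used for the posterior estimators
        (``parametric``, ``nonparametric`` or ``none`` = shrinkage off).
    batches : ordered batch registry; row order of the estimator arrays.
    alpha, sigma, beta : pooled mean (G,), pooled residual SD (G,),
        covariate coefficients (p, G) used for standardization.
    gamma_star, delta2_star : (B, G) posterior center-effect estimators.
    ref_batch, ref_alpha, ref_sigma : reference-batch rescaling moments,
        present only for the M-type variants.
    bootstrap : replicate count / seed metadata for B-type variants.
    """

    variant: str
    eb: str
    batches: list[str]
    feature_names: list[str]
    covariate_names: list[str]
    alpha: np.ndarray
    sigma: np.ndarray
    beta: np.ndarray
    gamma_star: np.ndarray
    delta2_star: np.ndarray
    ref_batch: str | None = None
    ref_alpha: np.ndarray | None = None
    ref_sigma: np.ndarray | None = None
    bootstrap: dict | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise SchemaError(f"unknown variant {self.variant!r}")
        if self.eb not in EB_MODES:
            raise SchemaError(f"unknown EB mode {self.eb!r}")
        for name in ("alpha", "sigma", "gamma_star", "delta2_star", "beta"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        g = len(self.feature_names)
        b = len(self.batches)
        if self.beta.size == 0 and not self.covariate_names:
            self.beta = np.empty((0, g))  # JSON [] loses the (0, G) shape
        if self.alpha.shape != (g,) or self.sigma.shape != (g,):
            raise SchemaError("global estimate shapes do not match feature count")
        if self.beta.shape != (len(self.covariate_names), g):
            raise SchemaError("covariate coefficient shape mismatch")
        if self.gamma_star.shape != (b, g) or self.delta2_star.shape != (b, g):
            raise SchemaError(
                "each registered batch needs a full estimator row "
                f"(expected {(b, g)}, got {self.gamma_star.shape} / "
                f"{self.delta2_star.shape})"
            )
        if not np.all(self.delta2_star > 0):
            raise SchemaError("delta2_star must be strictly positive")
        if not np.all(self.sigma > 0):
            raise SchemaError("sigma must be strictly positive")
        if self.is_reference_variant:
            if self.ref_batch is None:
                raise SchemaError("M-type variant requires a reference batch")
            if self.ref_batch not in self.batches:
                raise UnknownBatchError([self.ref_batch])
            self.ref_alpha = np.asarray(self.ref_alpha, dtype=float)
            self.ref_sigma = np.asarray(self.ref_sigma, dtype=float)
            if self.ref_alpha.shape != (g,) or self.ref_sigma.shape != (g,):
                raise SchemaError("reference moments do not match feature count")

    @property
    def is_reference_variant(self) -> bool:
        return self.variant in ("m-combat", "bm-combat")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "schema_version": SCHEMA_VERSION,
            "variant": self.variant,
            "eb": self.eb,
            "batches": list(self.batches),
            "feature_names": list(self.feature_names),
            "covariate_names": list(self.covariate_names),
            "alpha": self.alpha.tolist(),
            "sigma": self.sigma.tolist(),
            "beta": self.beta.tolist(),
            "gamma_star": {b: self.gamma_star[i].tolist()
                           for i, b in enumerate(self.batches)},
            "delta2_star": {b: self.delta2_star[i].tolist()
                            for i, b in enumerate(self.batches)},
            "ref_batch": self.ref_batch,
            "bootstrap": self.bootstrap,
            "meta": self.meta,
        }
        if self.is_reference_variant:
            d["ref_alpha"] = self.ref_alpha.tolist()
            d["ref_sigma"] = self.ref_sigma.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "HarmonizationModel":
        if not isinstance(d, dict) or "schema_version" not in d:
            raise SchemaError("not a harmonization model file")
        if d["schema_version"] != SCHEMA_VERSION:
            raise SchemaError(
                f"unsupported model schema version {d['schema_version']!r} "
                f"(this build reads version {SCHEMA_VERSION})"
            )
        required = ("variant", "eb", "batches", "feature_names",
                    "covariate_names", "alpha", "sigma", "beta",
                    "gamma_star", "delta2_star")
        missing = [k for k in required if k not in d]
        if missing:
            raise SchemaError("model file missing fields: " + ", ".join(missing))
        batches = list(d["batches"])
        for key in ("gamma_star", "delta2_star"):
            absent = [b for b in batches if b not in d[key]]
            if absent:
                raise SchemaError(
                    f"model file lacks {key} estimators for batch(es): "
                    + ", ".join(absent)
                )
        return cls(
            variant=d["variant"],
            eb=d["eb"],
            batches=batches,
            feature_names=list(d["feature_names"]),
            covariate_names=list(d["covariate_names"]),
            alpha=d["alpha"],
            sigma=d["sigma"],
            beta=d["beta"],
            gamma_star=np.array([d["gamma_star"][b] for b in batches], dtype=float),
            delta2_star=np.array([d["delta2_star"][b] for b in batches], dtype=float),
            ref_batch=d.get("ref_batch"),
            ref_alpha=d.get("ref_alpha"),
            ref_sigma=d.get("ref_sigma"),
            bootstrap=d.get("bootstrap"),
            meta=d.get("meta", {}),
        )

    def __eq__(self, other):
        if not isinstance(other, HarmonizationModel):
            return NotImplemented
        return self.to_dict() == other.to_dict()


def save_model(model: HarmonizationModel, path) -> None:
    """Write a model as versioned JSON.

    Floats are emitted via Python's shortest round-trip representation,
    so ``load_model(save_model(m))`` reproduces every value bit-for-bit.
    """
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model.to_dict(), fh, indent=1)
        fh.write("\n")


def load_model(path) -> HarmonizationModel:
    """Read a model written by :func:`save_model`."""
    try:
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"model file is not valid JSON (truncated?): {exc}") from exc
    return HarmonizationModel.from_dict(d)


def _align_covariates(model: HarmonizationModel,
                      X: CovariateMatrix | None,
                      n: int) -> np.ndarray:
    p = len(model.covariate_names)
    if p == 0:
        if X is not None and X.n_covariates:
            raise SchemaError("model was fitted without covariates but data has some")
        return np.zeros(n)  # broadcastable X @ beta term
    if X is None:
        raise SchemaError(
            "model expects covariates: " + ", ".join(model.covariate_names)
        )
    if set(X.column_names) != set(model.covariate_names):
        raise SchemaError(
            "covariate columns do not match the model schema "
            f"(expected {model.covariate_names}, got {X.column_names})"
        )
    order = [X.column_names.index(c) for c in model.covariate_names]
    return X.design[:, order] @ model.beta  # (n, G) in model feature order


def transform_new(model: HarmonizationModel,
                  Y_new: FeatureMatrix,
                  batches_new: BatchVector,
                  X_new: CovariateMatrix | None = None) -> FeatureMatrix:
    """Harmonize new samples from centers registered in a fitted model.

    The new data is standardized with the stored pooled estimates
    (alpha, sigma, beta) — nothing is re-estimated — and adjusted with the
    stored posterior estimators of each sample's batch.  Reference-batch
    rescaling is applied for M-type models.  Works for a single sample.

    Feature columns may appear in any order; they are realigned by name,
    and the output preserves the input column order.
    """
    names_new = Y_new.feature_names
    set_new, set_model = set(names_new), set(model.feature_names)
    if set_new != set_model:
        raise FeatureMismatchError(missing=set_model - set_new,
                                   extra=set_new - set_model)
    unknown = [b for b in batches_new.registry if b not in model.batches
               and batches_new.indices(b).size]
    if unknown:
        raise UnknownBatchError(unknown)
    if batches_new.n_samples != Y_new.n_samples:
        raise SchemaError("batch labels do not align with the feature matrix")

    # parameter vectors in the order of Y_new's columns
    pos = {f: i for i, f in enumerate(model.feature_names)}
    perm = np.array([pos[f] for f in names_new], dtype=int)
    alpha = model.alpha[perm]
    sigma = model.sigma[perm]

    xb = _align_covariates(model, X_new, Y_new.n_samples)
    if xb.ndim == 2:
        xb = xb[:, perm]
    else:
        xb = xb[:, None]  # zeros column, broadcasts over features

    z = (Y_new.values - alpha - xb) / sigma

    model_row = {b: i for i, b in enumerate(model.batches)}
    rows = np.array([model_row[b] for b in batches_new.labels], dtype=int)
    g_star = model.gamma_star[:, perm][rows]
    d_star = np.sqrt(model.delta2_star[:, perm][rows])

    if model.is_reference_variant:
        out_scale = model.ref_sigma[perm]
        out_loc = model.ref_alpha[perm]
    else:
        out_scale = sigma
        out_loc = alpha

    adjusted = (out_scale / d_star) * (z - g_star) + out_loc + xb
    return FeatureMatrix(adjusted, list(Y_new.sample_ids), list(names_new))
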