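"""Exception types shared across the package."""

from __future__ import annotations


class CombatKitError(Exception):
    """Base class for all combatkit errors."""


class ZeroVarianceError(CombatKitError):
    """Raised when one or more features carry no residual variance.

    Constant (or covariate-explained) features cannot be standardized;
    callers may drop the listed features and retry.
    """

    def __init__(self, feature_names):
        self.feature_names = list(feature_names)
        super().__init__(
            "features with zero residual variance: "
            + ", ".join(self.feature_names)
        )


class UnknownBatchError(CombatKitError):
    """Raised when data carries batch labels absent from a model's registry.

    Harmonizing samples from a center never seen at fit time is
    unsupported: no center-effect estimators exist for it.
    """

    def __init__(self, labels):
        self.labels = list(labels)
        super().__init__("unknown batch labels: " + ", ".join(map(str, self.labels)))


class BatchTooSmallError(CombatKitError):
    """Raised when a batch has fewer than two samples at fit time."""

    def __init__(self, batch):
        self.batch = batch
        super().__init__(
            f"batch {batch!r} has fewer than 2 samples; "
            "per-batch moments are undefined"
        )


class SchemaError(CombatKitError):
    """Raised on malformed input tables, configs or model files."""


class FeatureMismatchError(CombatKitError):
    """Raised when feature names of new data do not match a fitted model."""

    def __init__(self, missing, extra):
        self.missing = sorted(missing)
        self.extra = sorted(extra)
        parts = []
        if self.missing:
            parts.append("missing from data: " + ", ".join(self.missing))
        if self.extra:
            parts.append("not in model: " + ", ".join(self.extra))
        super().__init__("feature mismatch — " + "; ".join(parts))
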