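"""Statistical checks of harmonization quality and classifier metrics.

The battery used to judge whether center effects were removed:
per-feature one-way ANOVA across batch labels (fraction of features
significantly different between centers), two-sample Kolmogorov–Smirnov
comparison of distributions, coefficient-of-variation summaries, the
top-2 principal-component projection, Welch's unequal-variance t-test,
and binary-classifier metrics (ROC AUC, balanced accuracy, Matthews
correlation coefficient).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import (
    balanced_accuracy_score,
    matthews_corrcoef,
    roc_auc_score,
)
from sklearn.preprocessing import StandardScaler

from .containers import BatchVector, FeatureMatrix
from .errors import SchemaError

__all__ = ["batch_anova", "ks_two_sample", "cov_summary", "pca_top2",
           "welch_t", "classification_metrics", "diagnose",
           "DiagnosticsReport"]


def _values(Y) -> np.ndarray:
    return Y.values if isinstance(Y, FeatureMatrix) else np.asarray(Y, float)


def batch_anova(Y, batches: BatchVector, alpha: float = 0.01):
    """One-way fixed-effects ANOVA per feature across batch labels.

    Returns ``(p_values, fraction_significant)`` where the fraction is
    the share of features with p < alpha.  Features with zero
    within-group variance in every batch get the degenerate limit (p = 0
    if the group means differ, p = 1 if identical) with a warning.
    """
    vals = _values(Y)
    groups = [vals[batches.indices(b)] for b in batches.registry
              if batches.indices(b).size]
    if len(groups) < 2:
        raise SchemaError("ANOVA needs at least 2 batches")
    if any(g.shape[0] < 2 for g in groups):
        raise SchemaError("ANOVA needs at least 2 samples per batch")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = stats.f_oneway(*groups, axis=0)
    p = np.atleast_1d(np.asarray(p, float))
    degenerate = ~np.isfinite(p)
    if np.any(degenerate):
        means = np.stack([g.mean(axis=0) for g in groups])
        same = np.ptp(means, axis=0) == 0
        p[degenerate & same] = 1.0
        p[degenerate & ~same] = 0.0
        warnings.warn(
            f"{int(degenerate.sum())} feature(s) had zero within-batch "
            "variance; degenerate p-values substituted", stacklevel=2)
    return p, float(np.mean(p < alpha))


def ks_two_sample(a, b):
    """Classical two-sample Kolmogorov–Smirnov test (asymptotic p)."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.size == 0 or b.size == 0:
        raise SchemaError("KS test needs non-empty samples")
    if min(a.size, b.size) < 5:
        warnings.warn("KS asymptotic p-value is unreliable for n < 5",
                      stacklevel=2)
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def cov_summary(Y):
    """Per-feature coefficient of variation (percent) and its sum.

    COV_g = 100 * SD_g / |mean_g|.  Features with zero mean are excluded
    and reported; the aggregate is the sum over retained features (the
    per-feature vector is returned so any other aggregation can be
    recomputed).  Returns ``(per_feature, aggregate, excluded_names)``.
    """
    vals = _values(Y)
    names = (Y.feature_names if isinstance(Y, FeatureMatrix)
             else [str(i) for i in range(vals.shape[1])])
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    keep = np.abs(mean) > 1e-12 * np.maximum(sd, 1.0)
    excluded = [names[i] for i in np.flatnonzero(~keep)]
    if not np.any(keep):
        raise SchemaError("all features excluded from COV (zero means)")
    cov = np.full(vals.shape[1], np.nan)
    cov[keep] = 100.0 * sd[keep] / np.abs(mean[keep])
    return cov, float(np.nansum(cov)), excluded


def pca_top2(Y):
    """Top-2 principal components of the centered, unit-scaled features.

    Returns ``(coordinates (n, 2), explained_variance_fractions (2,))``.
    Component signs are fixed so the largest-magnitude loading of each
    axis is positive.
    """
    vals = _values(Y)
    n, g = vals.shape
    if n < 3 or g < 2:
        raise SchemaError("PCA needs n >= 3 samples and >= 2 features")
    sd = vals.std(axis=0)
    if np.count_nonzero(sd > 0) < 2:
        raise SchemaError("fewer than 2 non-degenerate features for PCA")
    scaled = StandardScaler().fit_transform(vals[:, sd > 0])
    pca = PCA(n_components=2)
    coords = pca.fit_transform(scaled)
    for k in range(2):
        j = np.argmax(np.abs(pca.components_[k]))
        if pca.components_[k, j] < 0:
            coords[:, k] *= -1.0
    return coords, pca.explained_variance_ratio_.astype(float)


def welch_t(a, b):
    """Welch's unequal-variance t-test, two-sided.

    Degenerate inputs (zero variance in both samples with equal means)
    return ``(0.0, 1.0)``.
    """
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.size < 2 or b.size < 2:
        raise SchemaError("Welch t-test needs n >= 2 in both samples")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.inf), 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def classification_metrics(y_true, scores, threshold: float = 0.5):
    """ROC AUC, balanced accuracy and Matthews correlation coefficient.

    AUC uses the rank (Mann–Whitney) formulation with tie mid-ranks.
    BAcc = (sensitivity + specificity) / 2 and MCC are computed at the
    given score threshold; MCC is 0 when a confusion-matrix margin is 0.
    Returns ``(auc, bacc, mcc)``.
    """
    y = np.asarray(y_true).astype(int).ravel()
    s = np.asarray(scores, float).ravel()
    if y.shape != s.shape:
        raise SchemaError("labels and scores must align")
    if len(np.unique(y)) < 2:
        raise SchemaError("both classes must be present in y_true")
    auc = float(roc_auc_score(y, s))
    pred = (s >= threshold).astype(int)
    bacc = float(balanced_accuracy_score(y, pred))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mcc = float(matthews_corrcoef(y, pred))
    return auc, bacc, mcc


@dataclass
class DiagnosticsReport:
    """Bundle of distributional diagnostics for one feature table."""

    anova_p: np.ndarray
    fraction_significant: float
    alpha: float
    cov_per_feature: np.ndarray
    cov_aggregate: float
    cov_excluded: list[str]
    pc_coordinates: np.ndarray
    explained_variance: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]
    batch_labels: list[str]

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "fraction_significant": self.fraction_significant,
            "anova_p": dict(zip(self.feature_names, self.anova_p.tolist())),
            "cov_per_feature": dict(zip(self.feature_names,
                                        self.cov_per_feature.tolist())),
            "cov_aggregate": self.cov_aggregate,
            "cov_excluded": self.cov_excluded,
            "explained_variance": self.explained_variance.tolist(),
        }


def diagnose(Y: FeatureMatrix, batches: BatchVector,
             alpha: float = 0.01) -> DiagnosticsReport:
    """Run the full diagnostic battery on one feature table."""
    p, frac = batch_anova(Y, batches, alpha)
    cov, agg, excl = cov_summary(Y)
    coords, evr = pca_top2(Y)
    return DiagnosticsReport(
        anova_p=p, fraction_significant=frac, alpha=alpha,
        cov_per_feature=cov, cov_aggregate=agg, cov_excluded=excl,
        pc_coordinates=coords, explained_variance=evr,
        feature_names=list(Y.feature_names),
        sample_ids=list(Y.sample_ids),
        batch_labels=[str(x) for x in batches.labels],
    )
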