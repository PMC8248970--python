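"""CSV readers/writers for feature tables.

Layout: one header row; a sample-identifier column and a batch-label
column are required; covariate and outcome columns are declared by name;
every remaining column is a numeric feature.  Samples are rows.  UTF-8,
'.' decimal.  Values are written with Python's shortest round-trip float
representation, so write → read is lossless.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import BatchVector, CovariateMatrix, FeatureMatrix
from .core import build_design
from .errors import SchemaError

__all__ = ["read_feature_csv", "write_feature_csv"]


def read_feature_csv(path, *, sample_col: str = "sample_id",
                     batch_col: str = "batch",
                     covariate_cols: tuple[str, ...] = (),
                     outcome_col: str | None = None):
    """Read a feature table.

    Returns ``(FeatureMatrix, BatchVector, CovariateMatrix, outcome)``
    where ``outcome`` is an int array or None.  Errors name the offending
    column, id, or cell.
    """
    df = pd.read_csv(path, dtype={sample_col: str, batch_col: str},
                     float_precision="round_trip")
    for col in (sample_col, batch_col, *covariate_cols,
                *((outcome_col,) if outcome_col else ())):
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing from {path}")

    ids = df[sample_col].astype(str)
    dup = ids[ids.duplicated()].unique()
    if dup.size:
        raise SchemaError("duplicate sample_id: " + ", ".join(dup))

    reserved = {sample_col, batch_col, *covariate_cols}
    if outcome_col:
        reserved.add(outcome_col)
    feature_cols = [c for c in df.columns if c not in reserved]
    if not feature_cols:
        raise SchemaError("no feature columns found")

    feats = df[feature_cols].apply(pd.to_numeric, errors="coerce")
    bad = feats.isna()
    if bad.any().any():
        r, c = np.nonzero(bad.to_numpy())
        cell_row, cell_col = int(r[0]), feature_cols[int(c[0])]
        raise SchemaError(
            f"non-numeric or missing feature value at row {cell_row + 2} "
            f"(sample {ids.iloc[cell_row]!r}), column {cell_col!r}")

    fm = FeatureMatrix(feats.to_numpy(float), list(ids), feature_cols)
    bv = BatchVector.from_labels(df[batch_col].astype(str).tolist())
    cov = build_design(df[list(covariate_cols)] if covariate_cols else None)
    if cov.n_covariates == 0:
        cov = CovariateMatrix.empty(len(df))

    outcome = None
    if outcome_col:
        out = pd.to_numeric(df[outcome_col], errors="coerce")
        if out.isna().any():
            raise SchemaError(f"outcome column {outcome_col!r} has missing values")
        outcome = out.to_numpy(int)
    return fm, bv, cov, outcome


def write_feature_csv(path, features: FeatureMatrix,
                      batches: BatchVector | None = None, *,
                      sample_col: str = "sample_id",
                      batch_col: str = "batch",
                      covariates: pd.DataFrame | None = None,
                      outcome=None, outcome_col: str = "outcome") -> None:
    """Write a feature table (full float precision)."""
    df = pd.DataFrame({sample_col: features.sample_ids})
    if batches is not None:
        df[batch_col] = list(batches.labels)
    if covariates is not None:
        for c in covariates.columns:
            df[c] = np.asarray(covariates[c])
    if outcome is not None:
        df[outcome_col] = np.asarray(outcome).astype(int)
    for j, name in enumerate(features.feature_names):
        # shortest round-trip representation, so write -> read is lossless
        df[name] = [repr(float(v)) for v in features.values[:, j]]
    df.to_csv(path, index=False)
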