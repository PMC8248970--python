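import numpy as np
import pytest

from combatkit import BatchVector, FeatureMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, prefix="s"):
    values = np.asarray(values, dtype=float)
    return FeatureMatrix(
        values,
        [f"{prefix}{i}" for i in range(values.shape[0])],
        [f"f{j}" for j in range(values.shape[1])],
    )


def make_batches(labels):
    return BatchVector.from_labels(labels)


@pytest.fixture
def three_batch_data(rng):
    """Small 3-batch table with injected location/scale effects."""
    sizes = {"A": 30, "B": 25, "C": 20}
    shifts = {"A": 0.0, "B": 1.2, "C": -0.8}
    scales = {"A": 1.0, "B": 1.6, "C": 0.7}
    g = 12
    rows, labels = [], []
    for b, n in sizes.items():
        rows.append(5.0 + shifts[b] + scales[b] * rng.standard_normal((n, g)))
        labels += [b] * n
    return make_matrix(np.vstack(rows)), make_batches(labels)
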