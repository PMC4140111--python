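import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def rand_index(a, b) -> float:
    """Fraction of sample pairs on which two partitions agree
    (label-permutation invariant)."""
    a = np.asarray(a)
    b = np.asarray(b)
    iu = np.triu_indices(len(a), 1)
    return float(np.mean((a[:, None] == a[None, :])[iu] == (b[:, None] == b[None, :])[iu]))


@pytest.fixture
def blobs3():
    """Three well-separated Gaussian blobs (n=45, 2-d), with labels."""
    g = np.random.default_rng(7)
    centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    labels = np.repeat([1, 2, 3], 15)
    X = centers[labels - 1] + g.normal(scale=1.0, size=(45, 2))
    return X, labels
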