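import numpy as np
import pytest

from swirls import ExpressionData, compute_centroid_set


def make_data(class0, class1, ids=None):
    class0 = np.atleast_2d(np.asarray(class0, float))
    class1 = np.atleast_2d(np.asarray(class1, float))
    if ids is None:
        ids = [f"g{i + 1}" for i in range(class0.shape[0])]
    return ExpressionData(class0, class1, tuple(ids))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_data(rng):
    """Random 5-gene dataset with mild class separation."""
    n0, n1 = 12, 15
    base = rng.normal(0, 2, (5, n0 + n1))
    shift = rng.normal(0.5, 0.5, 5)
    return make_data(base[:, :n0], base[:, n0:] + shift[:, None])


@pytest.fixture
def random_centroids(random_data):
    return compute_centroid_set(random_data)
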