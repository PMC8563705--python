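import numpy as np
import pytest

from smrt import OmicsMatrix


def make_layer(name, ids, values, feature_prefix="F"):
    values = np.asarray(values, dtype=float)
    return OmicsMatrix(
        name=name,
        sample_ids=list(ids),
        feature_ids=[f"{feature_prefix}{j}" for j in range(values.shape[1])],
        values=values,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def blob_layer(rng):
    """Three well-separated Gaussian blobs, 30 samples each, in 5 dimensions."""
    centers = np.array([[0.0] * 5, [10.0] * 5, [-10.0, 10.0, -10.0, 10.0, -10.0]])
    labels = np.repeat([1, 2, 3], 30)
    X = centers[labels - 1] + rng.normal(0, 1.0, size=(90, 5))
    layer = make_layer("blobs", [f"S{i:02d}" for i in range(90)], X)
    return layer, labels
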