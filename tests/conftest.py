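import numpy as np
import pytest

from mammocad import FeatureFixtureSpec, FeatureMatrix, make_features


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_feature_matrix(rng):
    """20 samples x 6 columns, two classes, no structure."""
    return FeatureMatrix(
        values=rng.standard_normal((20, 6)),
        labels=np.array(["a", "b"] * 10),
        backbone_id="fixture",
        source_id="fixture",
    )


@pytest.fixture
def separable_matrix():
    """Two well-separated point clouds: column 0 informative, column 1 noise."""
    rng = np.random.default_rng(7)
    n = 20
    col0 = np.concatenate([rng.normal(-10, 0.1, n), rng.normal(10, 0.1, n)])
    col1 = rng.standard_normal(2 * n)
    labels = np.array(["neg"] * n + ["pos"] * n)
    return FeatureMatrix(np.column_stack([col0, col1]), labels)


@pytest.fixture
def planted_small():
    """Small planted matrix with its ground-truth informative columns."""
    spec = FeatureFixtureSpec(
        n_per_class=30, d_informative=3, d_noise=7, effect_size=2.5, seed=11
    )
    return make_features(spec)
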