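import numpy as np
import pytest

from leaffuse.synthetic import (default_cluster_spec, default_recipes,
                                generate_feature_clusters, generate_leaf_image,
                                stratified_split)


@pytest.fixture(scope="session")
def healthy_leaf():
    """One 128x128 healthy leaf image with its ground-truth mask."""
    return generate_leaf_image(default_recipes()["Healthy"], 128, seed=7)


@pytest.fixture(scope="session")
def cluster_data():
    """Planted-confusable 6-class Gaussian feature clusters with a split."""
    spec = default_cluster_spec()
    shallow, depth, y = generate_feature_clusters(spec, n_per_class=60, seed=5)
    split = stratified_split(y, seed=6)
    return spec, shallow, depth, y, split


@pytest.fixture(scope="session")
def separable_features():
    """Two easily separable classes in 16 dimensions."""
    rng = np.random.default_rng(11)
    X = np.concatenate([rng.normal(-5, 1, (200, 16)), rng.normal(5, 1, (200, 16))])
    y = np.repeat([0, 1], 200)
    split = stratified_split(y, seed=12)
    return X, y, split
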