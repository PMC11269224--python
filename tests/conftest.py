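import numpy as np
import pytest

from saegbls import BLSArchitecture, NeighborGraphSpec, SaEConfig, synth_feature_clusters


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_clusters():
    """Well-separated two-class Gaussian features (fast to classify)."""
    return synth_feature_clusters(n_per_class=30, dim=4, separation=6.0, rng_seed=7)


@pytest.fixture
def tiny_arch():
    return BLSArchitecture(n_feature_groups=1, nodes_per_group=3, n_enhancement=4)


@pytest.fixture
def fast_sae():
    return SaEConfig(population_size=8, learning_period=2, max_generations=5, seed=3)


@pytest.fixture
def graph_spec():
    return NeighborGraphSpec(k1=3, k2=3)
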