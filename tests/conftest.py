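import numpy as np
import pytest

from targetrank import ClassifierConfig, SimConfig, simulate_labeled_features


@pytest.fixture(scope="session")
def informative_data():
    """Small, clearly separated synthetic dataset (signal in both blocks)."""
    config = SimConfig(n_pos=60, n_neg=60, embedding_dim=32, seed=11)
    block, labels = simulate_labeled_features(config)
    return config, block, labels


@pytest.fixture(scope="session")
def noise_data():
    """Exchangeable classes: no separation in any feature source."""
    config = SimConfig(
        n_pos=60,
        n_neg=60,
        embedding_dim=32,
        embedding_separation=0.0,
        omics_effect=0.0,
        mutation_rates=(0.1, 0.1),
        seed=11,
    )
    block, labels = simulate_labeled_features(config)
    return config, block, labels


@pytest.fixture
def fast_dnn_config():
    """Reduced-epoch dense-net config for protocol tests."""
    return ClassifierConfig(kind="dnn", epochs=10, seed=0)
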