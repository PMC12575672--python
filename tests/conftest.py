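import numpy as np
import pytest

from repliconn import SyntheticConfig, generate_features, generate_phenotype


@pytest.fixture(scope="session")
def small_dataset():
    """A 200-subject, 105-edge synthetic dataset with a strong planted effect."""
    cfg = SyntheticConfig(n_subjects=200, n_nodes=15, true_r2=0.25, seed=11)
    features = generate_features(cfg)
    planted = generate_phenotype(features, cfg)
    return cfg, features, planted


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
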