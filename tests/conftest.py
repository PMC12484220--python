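import numpy as np
import pytest

import scsoftclust as sc


@pytest.fixture(scope="session")
def tiny_spec():
    """A fast, well-separated simulated dataset spec for unit tests."""
    return sc.SyntheticSpec(
        n_cells=150, n_clusters=3, d_rna=60, d_atac=15,
        separation=8.0, noise_sd=0.5, frac_transitional=0.0, seed=7,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_spec):
    """Preprocessed version of the tiny dataset plus its true memberships."""
    ds, memberships = sc.generate(tiny_spec)
    return sc.preprocess(ds, n_top_features=2000), memberships


@pytest.fixture(scope="session")
def tiny_config():
    """A training config scaled for quick unit tests."""
    return sc.TrainingConfig(
        n_clusters=3, hidden=(32,), bottleneck=8, fused_dim=16,
        pretrain_epochs=15, train_epochs=8, patience=20,
        learning_rate=1e-3, seed=0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
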