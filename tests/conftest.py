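import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ac4cboost import (
    EncodingScheme,
    ModelConfig,
    SyntheticSpec,
    encode_dataset,
    generate_dataset,
    train,
)


@pytest.fixture(scope="session")
def small_dataset():
    """A quick separable dataset: 40 positives / 160 negatives, 51-nt."""
    spec = SyntheticSpec(n_pos=40, n_neg=160, length=51, enrichment_weight=6,
                         seed=7)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def small_matrix(small_dataset):
    seqs, y = small_dataset
    return encode_dataset(seqs, EncodingScheme.EIIP_PSEEIIP), y


@pytest.fixture(scope="session")
def fast_config():
    """Few trees, higher learning rate: for tests that only need a fit."""
    return ModelConfig(n_estimators=60, learning_rate=0.2, seed=11)


@pytest.fixture(scope="session")
def small_model(small_matrix, fast_config):
    X, y = small_matrix
    return train(X, y, fast_config)


@pytest.fixture(scope="session")
def default_fixture_dataset():
    """The full default synthetic benchmark (120/1080, 415 nt, seed 42)."""
    return generate_dataset(SyntheticSpec())


@pytest.fixture(scope="session")
def default_fixture_matrix(default_fixture_dataset):
    seqs, y = default_fixture_dataset
    return encode_dataset(seqs, EncodingScheme.EIIP_PSEEIIP), y
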