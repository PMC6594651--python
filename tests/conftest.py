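import numpy as np
import pytest

from convdti import DTIModel, ModelConfig
from convdti.encoding import CANONICAL_RESIDUES


@pytest.fixture
def tiny_config():
    """A minimal but fully featured architecture for fast structural tests."""
    return ModelConfig(
        window_sizes=(3, 4),
        filters_per_window=3,
        embedding_size=4,
        mpl=20,
        protein_dense_sizes=(5,),
        drug_dense_sizes=(4,),
        joint_dense_sizes=(4,),
        fingerprint_bits=10,
        spatial_dropout_rate=0.0,
        dense_dropout_rate=0.0,
        l2_lambda=0.0,
        seed=7,
    )


@pytest.fixture
def tiny_model(tiny_config):
    return DTIModel(tiny_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_sequence(rng, length):
    return "".join(rng.choice(list(CANONICAL_RESIDUES), size=length))


@pytest.fixture
def make_sequence(rng):
    return lambda length: random_sequence(rng, length)
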