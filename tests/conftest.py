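import numpy as np
import pytest

from milanova import BagSpec, ModelConfig, generate_bag_dataset, train_model

#: Reference separable bag-generator conditions: 100-patch bags where 20% of
#: patches are shifted 5 noise-sd along the class prototype.
SEPARABLE_SPEC = BagSpec(
    n_patches=100,
    feature_dim=64,
    signal_fraction=0.2,
    signal_strength=5.0,
    noise_sd=1.0,
    seed=1,
)

#: Small network sized for 64-dimensional features; keeps tests fast without
#: changing the architecture family (five 1x1 convs + MinMax + MLP).
SMALL_CONFIG = ModelConfig(
    feature_dim=64,
    conv_widths=(64, 32, 16, 8, 3),
    Nt=10,
    Nb=5,
    mlp_widths=(32,),
    dropout=0.2,
    epochs=20,
    seed=0,
)


@pytest.fixture(scope="session")
def separable_spec():
    return SEPARABLE_SPEC


@pytest.fixture(scope="session")
def train_bags():
    return generate_bag_dataset(SEPARABLE_SPEC, 20, seed=1)


@pytest.fixture(scope="session")
def eval_bags():
    return generate_bag_dataset(SEPARABLE_SPEC, 15, seed=2)


@pytest.fixture(scope="session")
def trained_model(train_bags):
    return train_model(train_bags, SMALL_CONFIG)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
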