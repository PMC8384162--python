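import numpy as np
import pytest

from g4net import (
    AccessibilityModel,
    ModelSpec,
    SyntheticConfig,
    generate_dataset,
    generate_toy_genome,
    train,
)


@pytest.fixture(scope="session")
def toy_genome():
    """Small planted-site genome shared by interval/scan tests."""
    return generate_toy_genome(
        n_chroms=2, chrom_length=60_000, n_active=15, n_decoy=8, seed=11
    )


@pytest.fixture(scope="session")
def small_dataset():
    config = SyntheticConfig(n_pos=300, n_neg=300, seed=3)
    dataset, annotations = generate_dataset(config)
    return dataset, annotations


@pytest.fixture(scope="session")
def small_model(small_dataset):
    """A quickly-trained model for unit tests that need fitted kernels."""
    dataset, _ = small_dataset
    spec = ModelSpec(n_kernels=32, epochs=8)
    return train(spec, dataset, seed=3)


@pytest.fixture(scope="session")
def interaction_model():
    """Model trained where the label needs both motif and accessibility."""
    config = SyntheticConfig(
        n_pos=600, n_neg=600, seed=5,
        accessibility_model=AccessibilityModel(interaction=True),
    )
    dataset, _ = generate_dataset(config)
    spec = ModelSpec(n_kernels=32, epochs=10)
    return train(spec, dataset, seed=5), dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
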