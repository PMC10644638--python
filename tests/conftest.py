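import numpy as np
import pytest

from diabsgan import (
    DCSGANConfig,
    SyntheticSpec,
    TabularDataset,
    generate_pima_like,
    generate_separable_gaussians,
)


@pytest.fixture(scope="session")
def pima_like():
    """Default synthetic PIMA-like dataset: 500:268 imbalance, zeros, outliers."""
    return generate_pima_like(SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def gaussian_fixture():
    """Two well-separated unit-variance Gaussian classes in 8 dimensions."""
    return generate_separable_gaussians(n=600, p=8, separation=8.0, n_classes=2, seed=3)


@pytest.fixture(scope="session")
def tiny_gan_config():
    """Small fast GAN config for unit tests that only need the mechanics."""
    return DCSGANConfig(
        latent_dim=8, gen_hidden=(16,), disc_hidden=(16,), epochs=5,
        batch_size=32, seed=0,
    )


@pytest.fixture
def toy_dataset():
    return TabularDataset(
        features=np.array([[0.0, 1.0], [4.0, 2.0], [6.0, 0.0], [2.0, 3.0], [8.0, 5.0]]),
        feature_names=["A", "B"],
        labels=np.array([0, 1, 0, 1, 0]),
    )
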