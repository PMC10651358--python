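import numpy as np
import pandas as pd
import pytest

from sitrans.data import AugmentationConfig, ImageAttributeDataset
from sitrans.frameworks import TrainingConfig
from sitrans.networks import CriticConfig, GeneratorConfig


def toy_dataset(n=6, size=16, m=2, seed=0, missing=False):
    """Small random-image dataset for exercising training mechanics."""
    rng = np.random.default_rng(seed)
    images = rng.random((n, size, size))
    attrs = pd.DataFrame(rng.normal(size=(n, m)), columns=[f"a{k+1}" for k in range(m)])
    if missing:
        attrs = attrs.mask(rng.random(attrs.shape) < 0.3)
    subjects = np.array([f"S{i % max(2, n // 2):03d}" for i in range(n)])
    return ImageAttributeDataset(images=images, attributes=attrs, subjects=subjects)


def tiny_training_config(framework, parameterization="sit_diff", **kw):
    """Deliberately tiny networks so training-loop tests stay fast."""
    defaults = dict(
        framework=framework,
        parameterization=parameterization,
        max_iterations=10,
        batch_size=4,
        seed=0,
        generator=GeneratorConfig(
            parameterization=parameterization,
            resolutions=2,
            bottom_channels=8,
            latent_dim=8,
            n_integration_steps=4,
            image_size=16,
        ),
        critic=CriticConfig(base_channels=4, n_down_blocks=2, hidden_dim=16, image_size=16),
        augmentation=AugmentationConfig(enabled=False),
        checkpoint_every=1000,
    )
    defaults.update(kw)
    return TrainingConfig(**defaults)


@pytest.fixture
def small_dataset():
    return toy_dataset()
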