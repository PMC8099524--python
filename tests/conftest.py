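import numpy as np
import pytest

from roigan import PhantomConfig, RoiCycleGan, generate_phantoms
from roigan.training import TrainConfig


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantoms16():
    """Small noisy textured phantom set for metric/feature tests."""
    cfg = PhantomConfig(image_size=64, n_samples=16, noise_sd=0.02,
                        texture_scale=6.0, seed=11)
    return generate_phantoms(cfg)


@pytest.fixture(scope="session")
def tiny_results():
    """A briefly-trained 32x32 model for synthesis contract tests (fast;
    fidelity is exercised separately at desk scale)."""
    samples = generate_phantoms(
        PhantomConfig(image_size=32, n_samples=4, noise_sd=0.0,
                      tumor_radius_range=(4, 7), seed=5))
    cfg = TrainConfig.desk_scale(seed=3, image_size=32, max_steps=30)
    return RoiCycleGan(samples, cfg).fit()


@pytest.fixture(scope="session")
def tiny_samples(tiny_results):
    return tiny_results.model.samples
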