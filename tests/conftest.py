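import numpy as np
import pytest

from bleedwatch.mtlnet import MTLUNet, NetConfig
from bleedwatch.scenegen import SceneScenario, generate_training_dataset


@pytest.fixture(scope="session")
def tiny_net_config() -> NetConfig:
    """Small architecture for fast structural tests."""
    return NetConfig(input_size=16, depth=2, base_channels=4, cls_hidden=8)


@pytest.fixture(scope="session")
def tiny_net(tiny_net_config) -> MTLUNet:
    return MTLUNet(tiny_net_config, seed=7)


@pytest.fixture(scope="session")
def small_dataset():
    """24 balanced 32x32 frames: enough to overfit quickly in tests."""
    return generate_training_dataset(24, seed=11, frame_size=32)


@pytest.fixture
def bleed_scenario() -> SceneScenario:
    return SceneScenario(
        duration_s=10.0,
        fps=25.0,
        precursor_onset_s=4.0,
        bleed_onset_s=7.0,
        rng_seed=3,
        background_texture_seed=3,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
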