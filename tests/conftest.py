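import numpy as np
import pytest

from rnaqdesign.environment import NussinovPredictor
from rnaqdesign.qnet import QNetwork, QNetworkConfig


@pytest.fixture(scope="session")
def tiny_config() -> QNetworkConfig:
    """Smallest network exercising every architectural component."""
    return QNetworkConfig(
        embed_dim=16, encoder_layers=1, decoder_layers=1, attention_heads=2,
        conv_kernel=3, gcn_layers=1, seed=7,
    )


@pytest.fixture(scope="session")
def tiny_network(tiny_config) -> QNetwork:
    return QNetwork(tiny_config)


@pytest.fixture(scope="session")
def predictor() -> NussinovPredictor:
    return NussinovPredictor()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
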