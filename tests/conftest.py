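import numpy as np
import pytest

from hrstnet import NetworkConfig, HRSTNet, generate_phantom, preprocess


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_cfg():
    """Smallest sensible network: 2 stages, 12-wide embedding, 4^3 windows."""
    return NetworkConfig(num_stages=2, embed_dim=12, window_size=(4, 4, 4),
                         in_channels=4, num_classes=4, seed=0)


@pytest.fixture(scope="session")
def tiny_model(tiny_cfg):
    return HRSTNet(tiny_cfg)


@pytest.fixture(scope="session")
def phantom_cases():
    """Eight preprocessed 32^3 phantoms (the overfit-study conditions)."""
    cases = []
    for i in range(8):
        ph = generate_phantom(1000 + i, 32)
        img, lab = preprocess(ph.image, ph.labels, 32, "eval")
        cases.append((img, lab))
    return cases
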