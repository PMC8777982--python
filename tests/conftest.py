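import numpy as np
import pytest

from vesselseg.data import SamplePair
from vesselseg.synth import VesselTreeParams, generate_dataset


@pytest.fixture(scope="session")
def tiny_pairs():
    """Ten 48x48 synthetic pairs shared across tests (read-only)."""
    return generate_dataset(10, VesselTreeParams(size=48), seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def checker_pair():
    """A deterministic hand-made pair: vertical vessel stripe."""
    img = np.zeros((16, 16, 3), np.uint8)
    img[:] = 180
    mask = np.zeros((16, 16), np.uint8)
    mask[:, 6:9] = 1
    img[mask == 1] = 60
    return SamplePair(id="stripe", image=img, mask=mask)
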