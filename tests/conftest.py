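import numpy as np
import pytest

from trabtex import GrayVolume, build_neighborhood


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def nbhd():
    return build_neighborhood(1.0)


@pytest.fixture
def random_volume(rng):
    """Continuous-valued random volume (no exact intensity ties)."""
    return GrayVolume(rng.uniform(0.0, 255.0, size=(12, 12, 12)), 27.8)


@pytest.fixture
def ramp_volume():
    """Strictly increasing intensity along the distal-proximal axis."""
    z = np.arange(16, dtype=np.float64)
    data = np.broadcast_to(40.0 + 10.0 * z, (16, 16, 16)).copy()
    return GrayVolume(data, 27.8)
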