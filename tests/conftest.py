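import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_synth():
    """Small in-memory synthetic image set shared across tests."""
    from qcsanet.data import SynthConfig, synthesize_arrays

    x, y = synthesize_arrays(30, SynthConfig(image_size=50), seed=7)
    return x, y
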