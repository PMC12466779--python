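import numpy as np
import pytest

from poredyn.constants import default_context


@pytest.fixture(scope="session")
def ctx():
    """The study's spectrometer context (14.1 T, 599.1 MHz 1H, 10 kHz lock)."""
    return default_context()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
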