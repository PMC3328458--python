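import numpy as np
import pytest

from bzdyn import build_duplex


@pytest.fixture(scope="session")
def b_duplex():
    """Canonical 10-bp B-form d(GC)5 duplex."""
    return build_duplex("GC", "B", 5)


@pytest.fixture(scope="session")
def z_duplex():
    """Canonical 10-bp Z-form d(GC)5 duplex."""
    return build_duplex("GC", "Z", 5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
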