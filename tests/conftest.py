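import numpy as np
import pytest

from rnpfootprint.core import ProtectedInterval, Transcript
from rnpfootprint.synth import toy_u2_reference


@pytest.fixture(scope="session")
def toy16():
    """16-nt transcript with a central protected interval: one upstream C,
    an oligo(U)-bearing protected block, purine runs, one downstream C."""
    return Transcript("TOY", "CAAAGAUUUUGAAAGC")


@pytest.fixture(scope="session")
def toy16_protection():
    return ProtectedInterval("TOY", 5, 11, "Sm")


@pytest.fixture(scope="session")
def u2():
    """Built-in synthetic U2-like reference and its protection annotations."""
    return toy_u2_reference()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
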