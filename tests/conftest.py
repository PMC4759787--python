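import numpy as np
import pytest

from dsbkin import MCF7, MDA_MB_468, AssumedConstants


@pytest.fixture(scope="session")
def mcf7():
    return MCF7


@pytest.fixture(scope="session")
def mda():
    return MDA_MB_468


@pytest.fixture(scope="session")
def constants():
    return AssumedConstants()


@pytest.fixture(scope="session")
def grid24():
    """25-point observation grid over the 24 h incubation."""
    return np.linspace(0.0, 24.0, 25)
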