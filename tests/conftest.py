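import numpy as np
import pytest

from avnode.presets import sodium_inact_fast_tau
from avnode.registry import load_registry


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def inact_fast_tau():
    """The printed fast-inactivation time-constant parameterization."""
    return sodium_inact_fast_tau()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
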