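import numpy as np
import pytest

from silkbundle.forcefield import ForceFieldParams


@pytest.fixture(scope="session")
def ff() -> ForceFieldParams:
    """Default (calibrated) force-field parameter set."""
    return ForceFieldParams()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
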