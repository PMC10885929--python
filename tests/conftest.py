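import numpy as np
import pytest

from hemocond import BloodParams


@pytest.fixture(scope="session")
def params() -> BloodParams:
    """Default blood parameters (physiological constants, H = 0.45)."""
    return BloodParams()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240201)
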