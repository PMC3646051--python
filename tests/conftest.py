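import numpy as np
import pytest

from trisoscan import load_rs2837770_triads


@pytest.fixture(scope="session")
def triads():
    """The packaged 26-triad rs2837770 table (trisomic children, A-dosage)."""
    return load_rs2837770_triads()


@pytest.fixture()
def rng():
    return np.random.default_rng(20130506)
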