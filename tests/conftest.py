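import numpy as np
import pytest

from ifomics.synth import SynthConfig, generate_study


@pytest.fixture(scope="session")
def study():
    """One default synthetic study shared by read-only tests."""
    return generate_study(SynthConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
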