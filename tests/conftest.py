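import numpy as np
import pytest

from apa_htp.workbench import generate_reference_fixture


@pytest.fixture(scope="session")
def fixture5():
    """Reference phantom/fields/partition at 5 mm spacing (desk scale)."""
    return generate_reference_fixture(seed=1, spacing_mm=5.0)


@pytest.fixture(scope="session")
def fixture8():
    """Coarser variant for tests that only need shapes and plumbing."""
    return generate_reference_fixture(seed=1, spacing_mm=8.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
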