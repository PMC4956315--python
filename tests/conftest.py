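import numpy as np
import pytest

from vesselseg.synthetic import default_spec, render, thin_spec, wide_spec


@pytest.fixture(scope="session")
def default_sample():
    """One default mixed-width synthetic fundus sample."""
    return render(default_spec(seed=1))


@pytest.fixture(scope="session")
def thin_sample():
    """Thin-only phantom (vessel widths 1-2 px)."""
    return render(thin_spec(seed=2))


@pytest.fixture(scope="session")
def wide_sample():
    """Wide-only phantom (vessel widths 6-8 px)."""
    return render(wide_spec(seed=2))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
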