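import numpy as np
import pytest

from kapurseg import GTOParams, PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_phantom():
    """One default-condition phantom with ground truth (seed 0)."""
    return generate_phantom(PhantomSpec(), np.random.default_rng(0))


@pytest.fixture
def small_gto_params():
    """Cheap optimizer settings for plumbing tests."""
    return GTOParams(n_agents=6, max_iters=10)
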