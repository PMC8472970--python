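import numpy as np
import pytest

from vesselseg.synthvessel import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """A 96x96 phantom shared across tests (generation is deterministic)."""
    return generate_phantom(PhantomSpec(height=96, width=96, n_trees=4,
                                        width_range=(1, 4), seed=7))


@pytest.fixture(scope="session")
def drive_sized_phantom():
    """One phantom at the 565x584 benchmark geometry."""
    return generate_phantom(PhantomSpec(seed=11))
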