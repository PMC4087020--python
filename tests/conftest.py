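import numpy as np
import pytest

from micellemix.synth import ToySimSpec, run_toy_aggregation

TOY_SEED = 1


@pytest.fixture(scope="session")
def toy_traj():
    """One default toy aggregation run, shared across the suite."""
    return run_toy_aggregation(ToySimSpec(seed=TOY_SEED))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
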