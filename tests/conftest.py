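import numpy as np
import pytest

from becseq import pipeline, simulate


@pytest.fixture(scope="session")
def study():
    """One default synthetic study run end to end (shared, read-only)."""
    return pipeline.run_study(seed=1)


@pytest.fixture(scope="session")
def default_config():
    return simulate.SimulationConfig(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
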