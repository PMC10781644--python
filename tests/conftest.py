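import numpy as np
import pytest

from morphlocus import synthio
from morphlocus.cli_io import RunConfig


@pytest.fixture(scope="session")
def tiny_config() -> RunConfig:
    """Heavily scaled-down profile for fast unit tests (1:100 architecture)."""
    return RunConfig(
        seed=11,
        scale_factor=100.0,
        n_per_morph=5,
        coverage=10.0,
        read_length=100,
        error_rate=0.0,
        mac=3,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return synthio.simulate_population(tiny_config)


@pytest.fixture(scope="session")
def tiny_reads(tiny_cohort):
    return synthio.cohort_reads(tiny_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
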