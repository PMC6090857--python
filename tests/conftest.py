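import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from m6apred import SimulationConfig, simulate_corpus

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_corpus():
    """~450-sample 10:1 corpus for cheap end-to-end exercises."""
    return simulate_corpus(SimulationConfig(n_transcripts=12, random_seed=3))


@pytest.fixture(scope="session")
def medium_corpus():
    """~2000-sample 10:1 corpus matching the planted-signal study size."""
    return simulate_corpus(SimulationConfig(n_transcripts=55, random_seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rna(rng, length):
    return "".join(rng.choice(list("ACGU"), size=length))
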