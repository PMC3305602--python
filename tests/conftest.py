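import pytest
from hypothesis import settings

from gemsim import fixtures

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def genome5k():
    """A 5 kb random genome shared by read-level tests."""
    return fixtures.random_genome(5000, 0.5, seed=11, name="ref")


@pytest.fixture(scope="session")
def genome1k_circular():
    return fixtures.random_genome(1000, 0.5, seed=12, name="circ", circular=True)
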