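import numpy as np
import pytest
from hypothesis import settings

from simpop import fixtures

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_bundle():
    """One moderately sized synthetic fixture bundle shared across tests."""
    return fixtures.default_fixtures(seed=42, n_households=600)


@pytest.fixture(scope="session")
def rate_tables(fixture_bundle):
    return fixture_bundle.rates


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def binomial_3se(p: float, n: int) -> float:
    """Three binomial standard errors on a proportion."""
    return 3.0 * np.sqrt(p * (1.0 - p) / n)
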