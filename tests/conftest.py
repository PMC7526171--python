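import pytest

from caulomsg import NutrientSignal, default_params


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def rich():
    """Ammonia with high carbon."""
    return NutrientSignal(Gln=10000.0, PEP=300.0, Pyr=1500.0)


@pytest.fixture(scope="session")
def nitrogen_starved():
    return NutrientSignal(Gln=1.0, PEP=300.0, Pyr=1500.0)


@pytest.fixture(scope="session")
def carbon_limited():
    return NutrientSignal(Gln=1000.0, PEP=2800.0, Pyr=900.0)
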