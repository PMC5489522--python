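import pytest

from ricesalt import (
    TraitParameters,
    AuxiliaryConstants,
    HostParameters,
    make_weather,
)


@pytest.fixture(scope="session")
def traits():
    return TraitParameters()


@pytest.fixture(scope="session")
def aux():
    return AuxiliaryConstants()


@pytest.fixture(scope="session")
def host():
    return HostParameters()


@pytest.fixture(scope="session")
def short_weather():
    """A deterministic 60-day synthetic season used by fast engine tests."""
    return make_weather(60, seed=42)


@pytest.fixture(scope="session")
def season_weather():
    """A deterministic full-length synthetic season."""
    return make_weather(150, seed=7)
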