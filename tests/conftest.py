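import dataclasses

import pytest

from crossnovex import FixtureConfig, generate_fixture


@pytest.fixture(scope="session")
def default_fixture():
    """The default-scale fixture (5% divergence, 2 target species)."""
    return generate_fixture(FixtureConfig(seed=0))


@pytest.fixture(scope="session")
def zero_divergence_fixture():
    """Planted copies are exact substrings of the target chromosomes."""
    return generate_fixture(
        dataclasses.replace(FixtureConfig(seed=0), divergence=0.0)
    )
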