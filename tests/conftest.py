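import pytest

from dietcost import (
    FixtureSpec,
    HDBSpec,
    generate_market,
    load_requirement_profile,
)


@pytest.fixture(scope="session")
def profile():
    return load_requirement_profile()


@pytest.fixture(scope="session")
def hdb():
    return HDBSpec.default()


@pytest.fixture(scope="session")
def market7(profile):
    """Default synthetic market: seed 7, three items per HDB group."""
    return generate_market(FixtureSpec(seed=7), profile)
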