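import pytest

from foodpatterns import fixture_bundle


@pytest.fixture(scope="session")
def bundle():
    """Calibrated fixture bundle shared across the suite."""
    return fixture_bundle(seed=0)


@pytest.fixture(scope="session")
def hvdp(bundle):
    return bundle.compositions["HVDP"]
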