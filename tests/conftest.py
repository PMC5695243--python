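import pytest

from ndhscan.simulate import cymbidium_like, make_reference


@pytest.fixture(scope="session")
def reference():
    """One deterministic toy plastome shared across tests."""
    return make_reference(seed=7)


@pytest.fixture(scope="session")
def preset():
    """Full study-conditions preset (degradations, chondriome, variants)."""
    return cymbidium_like(seed=7)
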