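import pytest

from stovesim import DEFAULT_KITCHEN, builtin_registry


@pytest.fixture(scope="session")
def registry():
    return builtin_registry()


@pytest.fixture(scope="session")
def kitchen():
    return DEFAULT_KITCHEN
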