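import pytest

from isoinchi import MOLECULE_POOL, parse


@pytest.fixture(scope="session")
def pool():
    """Parsed models of the vendored molecule pool, keyed by name."""
    return {name: parse(s) for name, s in MOLECULE_POOL.items()}


@pytest.fixture(scope="session")
def glucose():
    return MOLECULE_POOL["alpha_d_glucopyranose"]


@pytest.fixture(scope="session")
def g6p():
    return MOLECULE_POOL["glucosamine_6_phosphate"]


@pytest.fixture(scope="session")
def ethane():
    return MOLECULE_POOL["ethane"]
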