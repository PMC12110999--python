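import pytest

from contibd.genmap import fixture_map, toy_map
from contibd.pedigree import build_relationship


@pytest.fixture(scope="session")
def autosomes():
    return fixture_map()


@pytest.fixture(scope="session")
def toy():
    return toy_map()


@pytest.fixture(scope="session")
def rel():
    """Cached relationship factory (pedigrees and their chains are reused)."""
    cache = {}

    def get(token):
        if token not in cache:
            cache[token] = build_relationship(token)
        return cache[token]

    return get
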