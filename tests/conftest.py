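import pytest
from hypothesis import settings

from phaseq import synthetic_library as fixture

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def template():
    return fixture.twister_template()


@pytest.fixture(scope="session")
def inserts():
    return fixture.twister_insert_set()


@pytest.fixture(scope="session")
def layout():
    return fixture.twister_layout()


@pytest.fixture(scope="session")
def reduced_template():
    return fixture.reduced_template(2)
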