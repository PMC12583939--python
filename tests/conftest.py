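import pytest

from soagraph import fixtures


@pytest.fixture(scope="session")
def fig1():
    return fixtures.example_fig1()


@pytest.fixture(scope="session")
def fig2b():
    return fixtures.example_fig2b()


@pytest.fixture(scope="session")
def fig4():
    return fixtures.example_fig4()


@pytest.fixture(scope="session")
def corpus28():
    return fixtures.corpus(seed=0)
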