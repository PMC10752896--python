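import pytest

from codongc import load_code


@pytest.fixture(scope="session")
def standard():
    return load_code(1)


@pytest.fixture(scope="session")
def karyorelict():
    return load_code("Karyorelict Nuclear")


@pytest.fixture(scope="session")
def thraustochytrium():
    return load_code(23)
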