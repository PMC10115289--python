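import pytest

from cycleval.synthetic import coventry_fixture


@pytest.fixture(scope="session")
def coventry():
    return coventry_fixture()
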