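import pytest
from hypothesis import settings

from spliceaso import build_fixture_locus

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def locus():
    return build_fixture_locus()
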