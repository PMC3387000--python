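import pytest

from togascreen import make_reference_set


@pytest.fixture(scope="session")
def reference_porins():
    """Reference porin set for the relative beta-range criterion."""
    return make_reference_set(999)
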