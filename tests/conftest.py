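import pytest

from darwinsim.fixed_point import FixedPointFormat


@pytest.fixture(scope="session")
def q88() -> FixedPointFormat:
    """The default Q8.8 format used by most fixtures."""
    return FixedPointFormat()
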