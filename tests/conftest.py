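import pytest

from dsbquant import default_panel


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def hourly():
    """Hourly sampling 0-8 h, the standard resection time course."""
    return [float(t) for t in range(9)]
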