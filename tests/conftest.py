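import pytest

from combsyn.study import hela_fit


@pytest.fixture(scope="session")
def cisplatin_fit():
    """Two-point median-effect model pinned to the printed cisplatin IC50/IC75."""
    return hela_fit("cisplatin")


@pytest.fixture(scope="session")
def bc7_fit():
    """Two-point median-effect model pinned to the printed BC-7 IC50/IC75."""
    return hela_fit("BC-7")
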