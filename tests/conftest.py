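import pytest

from npkfis import default_system


@pytest.fixture(scope="session")
def system():
    """The packaged default NPK system (validated once per session)."""
    return default_system()
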