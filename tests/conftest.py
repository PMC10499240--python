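import pytest

from phylomod.scoring import ScoringModel


@pytest.fixture(scope="session")
def scoring():
    """One scoring model per session; weight tables are cached on it."""
    return ScoringModel()
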