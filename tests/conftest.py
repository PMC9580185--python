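import pytest
from hypothesis import settings

from dgecast import build_tag_catalog, simulate

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def transcriptome():
    """50 genes, all with unique tags."""
    return simulate.gen_transcriptome(50, seed=11)


@pytest.fixture(scope="session")
def catalog(transcriptome):
    return build_tag_catalog(transcriptome.records)


@pytest.fixture(scope="session")
def library_pair(transcriptome):
    """Null pair (no planted DE) at moderate depth."""
    return simulate.gen_library_pair(transcriptome, 50_000, 50_000, n_de=0, seed=5)
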