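import pytest

from meltmark.hrm import HRMConfig
from meltmark.sparidae import bundled_panel, bundled_primers, reference_genomes


@pytest.fixture(scope="session")
def genomes():
    """Synthetic species reference genomes (deterministic default seed)."""
    return reference_genomes()


@pytest.fixture(scope="session")
def primers():
    return bundled_primers()


@pytest.fixture(scope="session")
def panel():
    return bundled_panel()


@pytest.fixture()
def hrm_config():
    return HRMConfig()
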