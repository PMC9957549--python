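import numpy as np
import pytest

from alloanchor.haplotypes import load_panel_fixture


@pytest.fixture(scope="session")
def fixture_panel():
    """The packaged CD99 panel, registry and serology assignments."""
    return load_panel_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20231)


@pytest.fixture(scope="session")
def pooled_recovery_study():
    """One 200-replicate pooled-GWAS recovery study shared across tests."""
    from alloanchor.experiments import pooled_gwas_recovery

    return pooled_gwas_recovery(seed=1)
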