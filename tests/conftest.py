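import numpy as np
import pytest

from ampliclone.panel import simulate_panel, study_panel


@pytest.fixture(scope="session")
def small_panel():
    """Three sites on three chromosomes, 400-nt amplicons."""
    return simulate_panel(3, seed=42)


@pytest.fixture(scope="session")
def panel15():
    """The 15-site study panel."""
    return study_panel()


@pytest.fixture()
def rng():
    return np.random.default_rng(20210)
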