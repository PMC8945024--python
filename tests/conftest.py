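import numpy as np
import pytest

from monostim import synthetic
from monostim.design import build_design


@pytest.fixture(scope="session")
def design3():
    return build_design(n_donors=3, timepoints={0, 4, 24})


@pytest.fixture(scope="session")
def small_study():
    """Shared desk-scale synthetic study (kept small for test speed)."""
    return synthetic.simulate_study(n_probes=4000, n_genes=1200, seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
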