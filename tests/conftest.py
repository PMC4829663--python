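import numpy as np
import pytest

from h2atlas.cohort import SimScenario
from h2atlas.pipeline import simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest seven-component cohort shared by read-only tests."""
    scen = SimScenario(n_samples=300, n_snps=1500, n_causal=150, seed=11)
    return simulate_cohort(scen)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
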