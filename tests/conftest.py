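import numpy as np
import pytest

from trionurture import simtrio


@pytest.fixture(scope="session")
def small_cohort():
    """500 trios, 100 SNPs — cheap fixture for structural checks."""
    cfg = simtrio.SimConfig(n_trios=500, n_snps=100, seed=11)
    return simtrio.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def big_cohort():
    """20,000 trios with (c, m, f) = (0.15, 0.05, 0) for analytic identities."""
    cfg = simtrio.SimConfig(
        n_trios=20_000, n_snps=300, c=0.15, m=0.05, f=0.0, seed=17
    )
    return simtrio.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
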