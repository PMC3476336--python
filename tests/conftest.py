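import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20120831)


@pytest.fixture(scope="session")
def small_cohort():
    """A small CNV-free cohort reused across tests: 6 samples, 400 exons."""
    from bbcnv.simulate import SimConfig, simulate_counts

    cfg = SimConfig(n_samples=6, n_exons=400, seed=11, reads_per_exon=120.0,
                    phi=1e-3)
    return simulate_counts(cfg)
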