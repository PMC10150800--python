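import numpy as np
import pytest

from admixpress import sim


@pytest.fixture(scope="session")
def small_cohort():
    """One modest simulated study shared by read-only tests."""
    cfg = sim.SimConfig(
        n_anc_east=60, n_anc_west=60, n_admixed=50, n_sites=400, n_genes=10,
        fst_sim=0.2, alpha_west=0.5, generations=20.0, seed=11,
    )
    return sim.simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
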