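import numpy as np
import pytest

from bayesgc.model import BayesGC
from bayesgc.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """One small multi-breed dataset shared across tests (N=160, M=400)."""
    cfg = SimConfig(
        n_per_breed=(60, 50, 50), n_snps=400, n_chromosomes=2, n_qtl=5,
        h2=0.5, prop_var_qtl=0.6, seed=3,
    )
    data, truth = simulate_dataset(cfg)
    return cfg, data, truth


@pytest.fixture(scope="session")
def small_fit(small_sim):
    """A short two-chain fit of the small dataset, reused by mapping tests."""
    _, data, truth = small_sim
    model = BayesGC(
        data.y, data.genotypes, weights=data.weights,
        class_index=data.class_index,
    )
    res = model.fit(
        pi=0.01, sigma2_e=truth.sigma2_e, n_cycles=800, burn_in=200,
        n_chains=2, seed=11,
    )
    return model, res, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
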