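import numpy as np
import pytest

import cistrans as ct


@pytest.fixture(scope="session")
def small_sim() -> ct.SimResult:
    """A small but fully featured simulated cross shared across tests."""
    cfg = ct.SimConfig(
        n_genes=150,
        n_replicates=3,
        base_mean=400.0,
        dispersion=0.05,
        mean_snps_per_gene=3.0,
        seed=2024,
    )
    return ct.simulate_cross(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
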