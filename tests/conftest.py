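import numpy as np
import pandas as pd
import pytest

from permde import SimConfig, simulate_fpkm


@pytest.fixture(scope="session")
def small_sim():
    """A small planted-effect dataset shared across tests."""
    config = SimConfig(n_genes=400, frac_de=0.1, effect_size_log2=2.0,
                       noise_sd_log2=0.5, frac_silent=0.1, seed=11)
    fpkm, groups, truth = simulate_fpkm(config)
    return config, fpkm, groups, truth


@pytest.fixture
def tiny_fpkm():
    """Hand-written 4-gene, 4-sample FPKM matrix with a boundary row."""
    return pd.DataFrame(
        {
            "control_1": [0.5, 1.2, 1.0, 8.0],
            "control_2": [0.9, 0.1, 1.0, 9.0],
            "treated_1": [0.2, 0.3, 1.0, 30.0],
            "treated_2": [0.4, 0.2, 1.0, 40.0],
        },
        index=pd.Index(["low", "bursty", "boundary", "high"], name="gene_id"),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
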