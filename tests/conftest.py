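import numpy as np
import pytest

from pgsport.simulate import SimulationConfig, simulate_biobank


@pytest.fixture(scope="session")
def tiny_config():
    """Small three-deme world used by fast structural tests."""
    return SimulationConfig(
        n_gwas=600,
        n_pred_per_deme=(250, 200, 200),
        deme_fst=(0.001, 0.05, 0.2),
        m_variants=400,
        m_causal=80,
        h2=0.5,
        n_admixed_per_pair=0,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_sim(tiny_config):
    return simulate_biobank(tiny_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
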