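import numpy as np
import pytest

from snpher.simulate import SimulationConfig, simulate_panel, simulate_phenotypes
from snpher.qc import compute_grm


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_samples=600, n_variants=1200, master_seed=42, ld_block_length=20,
        ld_rho=0.6,
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    return simulate_panel(small_config)


@pytest.fixture(scope="session")
def small_phenotypes(small_config, small_panel):
    return simulate_phenotypes(small_panel, small_config)


@pytest.fixture(scope="session")
def small_grm(small_panel):
    return compute_grm(small_panel)


@pytest.fixture(scope="session")
def unlinked_panel():
    cfg = SimulationConfig(
        n_samples=800, n_variants=1500, master_seed=7, ld_block_length=1,
        ld_rho=0.0,
    )
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def unlinked_grm(unlinked_panel):
    return compute_grm(unlinked_panel)
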