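import numpy as np
import pytest

from eqtlcross.simulate import SimConfig, simulate_population


@pytest.fixture(scope="session")
def desk_sim():
    """Small default-architecture cohort shared by read-only tests."""
    cfg = SimConfig(
        n_per_backcross=(24, 24, 24), snps_per_chromosome=60, seed=42024
    )
    return simulate_population(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
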