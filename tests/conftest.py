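import numpy as np
import pytest

from motucomm import SimulationConfig, simulate_community


@pytest.fixture(scope="session")
def small_dataset():
    """A small, well-separated community: 20 species, clean divergences."""
    cfg = SimulationConfig(
        n_species=20, d_intra=0.01, d_inter=0.08, seed=11, n_sites=4
    )
    return simulate_community(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
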