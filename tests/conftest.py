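import numpy as np
import pytest

from magwas.simulate import make_variant_map, simulate_ld_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ar1_panel():
    """Single 20-variant AR-1 block with rho = 0.9."""
    return simulate_ld_matrix([20], [0.9])


@pytest.fixture
def block_panel():
    """Three independent AR-1 blocks of mixed size and correlation."""
    return simulate_ld_matrix([10, 15, 5], [0.9, 0.5, 0.0])
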