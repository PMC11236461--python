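import numpy as np
import pytest

from fragdiv.community import Beta4Params, CommunityConfig, simulate_community


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_community():
    """A fast 10-patch, 40-species community (areas capped at 500 Ha)."""
    cfg = CommunityConfig(
        n_patches=10,
        n_species=40,
        area_params=Beta4Params(alpha=1.0, beta=4.0, min=25.0, max=500.0),
    )
    return simulate_community(cfg, 7)


@pytest.fixture(scope="session")
def default_community():
    """One full-size community at published defaults."""
    return simulate_community(CommunityConfig(), 11)
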