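import numpy as np
import pytest

from r1hic.hicdata import ContactMap, divide_submatrices, scn_normalize
from r1hic.simulate import (
    SyntheticSpec,
    coarsen_map,
    downsample_map,
    simulate_contact_map,
)


def random_symmetric(n: int, seed: int = 0, nonneg: bool = True) -> np.ndarray:
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, n))
    if nonneg:
        x = np.abs(x)
    return 0.5 * (x + x.T)


@pytest.fixture(scope="session")
def sim_maps():
    """One simulated fine map with its 16x-thinned, 4x-coarsened twin."""
    spec = SyntheticSpec(num_bins=512, seed=1)
    hr = simulate_contact_map(spec)
    lr = coarsen_map(downsample_map(hr, 16, seed=2), 4)
    return hr, lr


@pytest.fixture(scope="session")
def norm_pairs(sim_maps):
    """SCN-normalized training submatrices (n=128, m=32) from sim_maps."""
    hr, lr = sim_maps
    hr_n, _ = scn_normalize(hr)
    lr_n, _ = scn_normalize(lr)
    return divide_submatrices(hr_n, lr_n, n=128)


@pytest.fixture
def small_map():
    counts = random_symmetric(32, seed=3)
    return ContactMap("chrT", 10_000, counts)
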