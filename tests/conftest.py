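import numpy as np
import pytest

import dtialps as d


@pytest.fixture(scope="session")
def osa_truth():
    """Default phantom: fiber-shell diffusivities at the OSA group means."""
    return d.build_phantom(d.PhantomSpec())


@pytest.fixture(scope="session")
def noiseless_dwi(osa_truth):
    return d.simulate_dwi(osa_truth)


@pytest.fixture(scope="session")
def noiseless_field(noiseless_dwi):
    mask = d.brain_mask(noiseless_dwi, 0.0)
    return d.fit_tensor_field(noiseless_dwi, mask)


@pytest.fixture(scope="session")
def small_truth():
    """Smaller phantom for repeated simulate-fit loops."""
    return d.build_phantom(d.PhantomSpec(grid_shape=(16, 16, 12)))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
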