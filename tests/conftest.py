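import numpy as np
import pytest

import phenolidar as pl


@pytest.fixture(scope="session")
def rcbd_design():
    """60-plot RCBD: 20 genotypes × 3 replicates."""
    return pl.simulate_design(20, "rcbd", 3, rng_seed=11)


@pytest.fixture(scope="session")
def small_design():
    return pl.simulate_design(10, "rcbd", 2, rng_seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20160523)


@pytest.fixture()
def random_cloud(rng):
    n = 50
    return pl.PointCloud(
        rng.uniform(0.0, 0.3, n), rng.uniform(0.0, 0.3, n), rng.uniform(0.0, 0.25, n)
    )
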