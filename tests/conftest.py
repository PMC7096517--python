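import numpy as np
import pytest

from sersrf import (
    ForestParams,
    SimulationConfig,
    fit_forest,
    simulate_study,
    spectral_grid,
)


@pytest.fixture(scope="session")
def grid():
    return spectral_grid()


@pytest.fixture(scope="session")
def small_study():
    """One tiny f=0.8 replicate (50 spectra per group) plus its library."""
    config = SimulationConfig(f=0.8, n_replicates=1, n_per_group=50, seed=3)
    library, datasets = simulate_study(config)
    return library, datasets[0]


@pytest.fixture(scope="session")
def tiny_forest():
    """Small forest on a 40x5 matrix with one informative variable,
    used by the brute-force oracle comparisons."""
    rng = np.random.default_rng(7)
    X = rng.normal(size=(40, 5))
    y = np.repeat([0, 1], 20)
    X[y == 1, 2] += 2.0
    model = fit_forest(X, y, ForestParams(ntree=10, mtry=3), random_state=11)
    return X, y, model
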