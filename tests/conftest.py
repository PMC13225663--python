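import numpy as np
import pytest

from placecells import Geometry, PlaceFieldParams, simulate_trials


@pytest.fixture
def geom50():
    return Geometry.linear(50)


@pytest.fixture
def grid10():
    return Geometry.grid(10, 10)


@pytest.fixture
def default_params():
    return PlaceFieldParams(a=10.0, mu=24.5, sigma=5.0, b0=1.0, noise_sd=1.0)


@pytest.fixture
def noisy_matrix(default_params, geom50):
    return simulate_trials(default_params, geom50, 30, seed=42)


def simulate_population(params, geom, n_neurons, n_trials=30, seed=0, **kw):
    """Small helper: n_neurons independent matrices with derived sub-seeds."""
    return [simulate_trials(params, geom, n_trials,
                            seed=np.random.SeedSequence((seed, i)), **kw)
            for i in range(n_neurons)]
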