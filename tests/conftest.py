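import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import craniomix as cm

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def scheme34():
    """Default 34-landmark scheme: 6 midline + 14 bilateral pairs."""
    return cm.SymmetryScheme.default(34)


@pytest.fixture(scope="session")
def study():
    """One full synthetic study at the default (study-scale) conditions."""
    params = cm.SimulationParams(seed=1)
    dataset, truth = cm.simulate_study(params)
    return params, dataset, truth


@pytest.fixture(scope="session")
def fitted_study(study):
    _, dataset, _ = study
    return cm.study.run_study(dataset)


@pytest.fixture
def small_sources(rng):
    """Small two-source dataset (n=10 per source) for cheap pipeline checks."""
    params = cm.SimulationParams(
        seed=7,
        group_sizes={cm.Group.DANISH: (5, 5), cm.Group.PREMED_BRITISH: (5, 5)},
    )
    dataset, truth = cm.simulate_study(params)
    return params, dataset, truth


def random_similarity(coords, rng):
    """Apply a random rotation + translation + positive scaling."""
    from craniomix.simulate import _random_rotation

    R = _random_rotation(rng)
    s = float(np.exp(rng.normal(0, 0.5)))
    t = rng.uniform(-10, 10, 3)
    return s * (coords @ R.T) + t
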