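import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import raschcir as rc

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def beta_fit():
    """A medium-sized continuous-response study: 300 units x 6 items,
    beta noise at precision 12, fitted with defaults."""
    spec = rc.SimulationSpec(300, 6, noise_mode="beta", beta_precision=12,
                             seed=11)
    matrix, truth = rc.simulate_matrix(spec)
    result = rc.fit(matrix)
    stats = rc.compute_fit_statistics(result)
    return matrix, truth, result, stats


@pytest.fixture(scope="session")
def binary_fit():
    """Dichotomous data (100 x 11) with extreme response strings removed."""
    spec = rc.SimulationSpec(100, 11, noise_mode="binary", seed=7)
    matrix, truth = rc.simulate_matrix(spec)
    matrix = rc.strip_extremes(matrix)
    result = rc.fit(matrix)
    return matrix, truth, result


@pytest.fixture
def small_matrix():
    values = np.array([
        [0.9, 0.4, 0.7],
        [0.2, 0.6, 0.1],
        [0.5, 0.5, 0.8],
        [0.7, 0.3, 0.6],
    ])
    return rc.ResponseMatrix(
        person_ids=["a", "b", "c", "d"],
        item_ids=["i1", "i2", "i3"],
        values=values,
        item_min=0.0,
        item_max=1.0,
    )
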