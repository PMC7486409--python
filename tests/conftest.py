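import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sefreq import DecompositionConfig, FrequencyMatrix
from sefreq.synth import SyntheticSpec, generate_frequency_matrix

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def tiny_matrix() -> FrequencyMatrix:
    """2x2 instance from the worked arithmetic examples."""
    return FrequencyMatrix(np.array([[5, 0], [0, 4]]), ["d1", "d2"], ["s1", "s2"])


@pytest.fixture
def small_random_matrix() -> FrequencyMatrix:
    rng = np.random.default_rng(42)
    values = rng.integers(0, 6, size=(12, 9))
    values[rng.random(values.shape) < 0.5] = 0
    return FrequencyMatrix(values, [f"d{i}" for i in range(12)], [f"s{j}" for j in range(9)])


@pytest.fixture(scope="session")
def synthetic_instance():
    """Default-condition synthetic matrix with its truth bundle (shared)."""
    spec = SyntheticSpec(seed=3)
    fm, truth = generate_frequency_matrix(spec)
    return fm, truth


@pytest.fixture(scope="session")
def fitted_synthetic(synthetic_instance):
    from sefreq import fit

    fm, _ = synthetic_instance
    model = fit(fm, DecompositionConfig(k=5, seed=1))
    return fm, model


def random_sparse_matrix(rng, n, m, density=0.3) -> FrequencyMatrix:
    values = rng.integers(1, 6, size=(n, m))
    values[rng.random((n, m)) >= density] = 0
    return FrequencyMatrix(values, [f"d{i}" for i in range(n)], [f"s{j}" for j in range(m)])
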