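import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

PERIOD = 24.0


def cosine(t, A, phi, M, period=PERIOD):
    return A * np.cos(2 * np.pi / period * (np.asarray(t, float) - phi)) + M


@pytest.fixture(scope="session")
def even24():
    """The standard collection design: 24 samples, one per hour."""
    return np.arange(24.0)


@pytest.fixture(scope="session")
def noisy_gene(even24):
    """One rhythmic gene (A=2, phi=6, M=10, sigma=1) with a fixed seed."""
    rng = np.random.default_rng(2024)
    y = cosine(even24, 2.0, 6.0, 10.0) + rng.normal(0, 1, even24.size)
    return y, even24


@pytest.fixture(scope="session")
def mixture_fixture():
    """The packaged 100-gene mixed-truth dataset (seed 42)."""
    from circadiff import simulate_tor_mixture

    return simulate_tor_mixture(seed=42)


@pytest.fixture(scope="session")
def mixture_results(mixture_fixture):
    from circadiff import run_pipeline

    ds, truth = mixture_fixture
    return run_pipeline(ds), truth
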