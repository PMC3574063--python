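import numpy as np
import pytest

from homclust import default_benchmark
from homclust import pipeline as pl


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def benchmark():
    """The pinned 109-sequence synthetic benchmark (seed 42)."""
    return default_benchmark(seed=42)


@pytest.fixture(scope="session")
def benchmark_inputs(benchmark):
    return pl.benchmark_inputs(benchmark)


def random_psd_kernel(rng, n, ids=None):
    """A random unit-diagonal PSD kernel (Gram matrix of random features)."""
    from homclust.kernels import Kernel, unit_sphere_normalize

    X = rng.normal(size=(n, max(2, n // 2)))
    G = X @ X.T + n * np.eye(n)  # keep the diagonal comfortably positive
    ids = ids or [f"s{i}" for i in range(n)]
    return unit_sphere_normalize(Kernel(ids, G))
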