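import numpy as np
import pytest

from peercourse import ModelParams, run


@pytest.fixture
def params():
    """Benchmark parameter set."""
    return ModelParams(seed=0)


@pytest.fixture(scope="session")
def benchmark_trajectory():
    """One full benchmark run, shared across read-only tests."""
    return run(ModelParams(seed=11), snapshot_times=(0, 1, 100, 200, 300))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
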