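import numpy as np
import pytest

from fscc.calibration import compute_base_statistics
from fscc.synthetic import FeatureBenchmarkConfig, generate_feature_benchmark


@pytest.fixture(scope="session")
def benchmark():
    """Standard feature-space benchmark: 8 base / 5 novel Gaussian classes, d=16."""
    return generate_feature_benchmark(FeatureBenchmarkConfig(seed=0))


@pytest.fixture(scope="session")
def benchmark_stats(benchmark):
    """Base-class statistics in the calibration pipeline's transformed space."""
    return compute_base_statistics(benchmark.base_features, benchmark.base_labels,
                                   tukey_lambda=0.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
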