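import numpy as np
import pytest

from methylsmr import AnalysisConfig, BenchmarkConfig, make_benchmark


@pytest.fixture(scope="session")
def bench():
    """Default miniature study: 3 traits x 60 loci, two tissues."""
    return make_benchmark(seed=7)


@pytest.fixture(scope="session")
def bench_with_expression():
    cfg = BenchmarkConfig(n_probes=24, n_traits=2, include_expression=True,
                          n_eqtl=2000, n_gwas=8000, seed=11)
    return make_benchmark(cfg)


@pytest.fixture()
def config():
    return AnalysisConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
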