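import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("det", derandomize=True, deadline=None)
settings.load_profile("det")

from sipgrade.gradient import build_layout
from sipgrade.synthetic import BenchmarkConfig


@pytest.fixture(scope="session")
def layout():
    return build_layout()


@pytest.fixture()
def small_config():
    """A quick community config for pipeline tests (not the benchmark)."""
    return BenchmarkConfig(n_taxa=8, length_meanlog=8.3, length_sdlog=0.4)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
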