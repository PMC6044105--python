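import numpy as np
import pytest

from kflr.io_formats import ExpressionDataset
from kflr.simulate import SimulationConfig, make_benchmark


@pytest.fixture
def small_dataset():
    """Deterministic 3-gene, 2-series dataset for I/O and plumbing tests."""
    rng = np.random.default_rng(42)
    series = [rng.standard_normal((6, 3)), rng.standard_normal((5, 3))]
    times = [np.arange(6.0), np.arange(5.0)]
    return ExpressionDataset(["G1", "G2", "G3"], series, times)


@pytest.fixture
def benchmark10():
    """One standard-size synthetic benchmark (10 genes, 5x21 series)."""
    return make_benchmark(SimulationConfig(seed=7))
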