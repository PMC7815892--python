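import numpy as np
import pytest

import mvbench as mb


@pytest.fixture(scope="session")
def design():
    return mb.spikein_design()


@pytest.fixture(scope="session")
def small_benchmark(design):
    """Complete desk-scale benchmark: 167 proteins x 32 samples."""
    counts = {"E.coli": 30, "yeast": 27, "human": 110}
    return mb.generate_benchmark(design, counts, seed=42)


@pytest.fixture(scope="session")
def masked_small(small_benchmark):
    """20% MV / 50% MNAR amputation of the small benchmark (log2)."""
    spec = mb.MissingnessSpec(alpha=0.2, beta=0.5, seed=3)
    return mb.simulate_missingness(small_benchmark.to_log2(), spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
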