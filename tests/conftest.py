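import numpy as np
import pytest

from nirgaf.synthetic import SyntheticConfig, generate, benchmark_presets


@pytest.fixture(scope="session")
def wheat_dataset():
    """The two-band two-class preset at its default size (100 per class)."""
    cfg = benchmark_presets()["wheat-like"]
    cfg.seed = 0
    return generate(cfg)


@pytest.fixture(scope="session")
def small_dataset():
    """A fast, strongly separable dataset for unit-level model tests."""
    cfg = SyntheticConfig(n_per_class=15, n_points=64, seed=7)
    return generate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
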