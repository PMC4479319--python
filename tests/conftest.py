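import numpy as np
import pytest

import strawsugar as ss


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded draw of the reference study conditions."""
    cfg = ss.SyntheticConfig(seed=1)
    spectra, responses, truth = ss.generate_dataset(cfg)
    return cfg, spectra, responses, truth


@pytest.fixture()
def small_spectra():
    """A tiny deterministic spectrum set for I/O and operator tests."""
    rng = np.random.default_rng(42)
    grid = ss.default_grid(1000, 604, 4)  # 100 points
    X = rng.random((5, grid.size)) + 0.5
    return ss.SpectrumSet(grid, X, [f"S{i}" for i in range(5)])
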