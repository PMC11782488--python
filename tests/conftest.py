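import numpy as np
import pytest

import spheromap as sp


@pytest.fixture(scope="session")
def small_benchmark():
    """Modest synthetic dataset shared by unit tests (fast to fit)."""
    cfg = sp.SimulationConfig(
        n_cells=800,
        median_depth=20_000,
        gene_blocks=[
            sp.GeneBlock("core", 15, magnitude_range=(0.5, 0.9)),
            sp.GeneBlock("periphery", 15, magnitude_range=(0.5, 0.9)),
            sp.GeneBlock("intermediate", 8, magnitude_range=(0.5, 0.9)),
            sp.GeneBlock("extrema", 8, magnitude_range=(0.5, 0.9)),
            sp.GeneBlock("flat", 30),
        ],
        seed=123,
    )
    cells, counts, truth = sp.make_benchmark(cfg)
    return cells, counts, truth


@pytest.fixture(scope="session")
def positioned_cells():
    """1,500 cells with r^2 density and lognormal depths (no counts)."""
    r = sp.sample_radial_positions(1500, seed=5)
    depth = sp.sample_depths(1500, 20_000, 0.4, seed=6)
    return r, depth.astype(float)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
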