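import numpy as np
import pytest

from phyloprior.grid import LandscapeGrid
from phyloprior.synthetic import SimulationConfig, simulate_landscape


@pytest.fixture(scope="session")
def grid10():
    return LandscapeGrid.regular(10, 10, 20.0)


@pytest.fixture(scope="session")
def small_landscape():
    """One modest synthetic landscape reused by read-only tests."""
    cfg = SimulationConfig(nx=15, ny=15, n_species=40, min_occ=8, seed=7)
    return simulate_landscape(cfg)


def random_presences(rng: np.random.Generator, n_species: int, n_cells: int,
                     p: float = 0.3) -> np.ndarray:
    """Random occupancy with every species occupying >= 1 cell."""
    occ = rng.random((n_species, n_cells)) < p
    for i in range(n_species):
        if not occ[i].any():
            occ[i, rng.integers(n_cells)] = True
    return occ
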