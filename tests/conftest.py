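import numpy as np
import pytest

from noisescape import landscape as land
from noisescape import synthetic as syn


@pytest.fixture(scope="session")
def win_grid():
    """Standard analysis grid around wt = 4 (61 x 81 points)."""
    return land.make_grid(4.0)


@pytest.fixture(scope="session")
def ext_grid():
    """Extended grid covering the full promoter expression range [2, 6]."""
    return land.make_grid(4.0, mean_halfwidth=2.0)


@pytest.fixture(scope="session")
def basis(win_grid):
    return syn.PrincipalTopologyBasis(win_grid)


@pytest.fixture(scope="session")
def panel80():
    return syn.generate_promoter_panel(
        syn.SyntheticPanelConfig(n_promoters=80, seed=12))


@pytest.fixture(scope="session")
def peaked_landscape(win_grid):
    truth = syn.peaked_truth(4.0)
    return land.FitnessLandscape(grid=win_grid, f=truth.surface(win_grid),
                                 total_weight=np.ones(win_grid.shape),
                                 gene="peaked")


@pytest.fixture(scope="session")
def shortage_landscape(win_grid):
    truth = syn.shortage_truth(4.0)
    return land.FitnessLandscape(grid=win_grid, f=truth.surface(win_grid),
                                 total_weight=np.ones(win_grid.shape),
                                 gene="shortage")


def make_landscape(grid, f):
    """Wrap an array as a FitnessLandscape with unit weights."""
    return land.FitnessLandscape(grid=grid, f=np.asarray(f, dtype=float),
                                 total_weight=np.ones(grid.shape))
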