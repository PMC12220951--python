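import numpy as np
import pandas as pd
import pytest

from gmscreen import qibc, simulate


@pytest.fixture(scope="session")
def small_screen():
    """A compact simulated screen shared by several test modules."""
    params = simulate.ScreenSimParams(
        n_genes=30, n_hit_genes=3, cells_per_well=300, seed=11
    )
    cells, truth = simulate.gen_screen_cells(params)
    return params, cells, truth


@pytest.fixture(scope="session")
def small_screen_wells(small_screen):
    """Per-well percent-positive table derived from the compact screen."""
    _, cells, _ = small_screen
    frames = []
    for _, sub in cells.groupby("cell_line"):
        thresholds = qibc.plate_thresholds(sub, "gH2AX_mean")
        frames.append(qibc.well_positive_fractions(sub, thresholds))
    return pd.concat(frames, ignore_index=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
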