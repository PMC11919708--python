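import numpy as np
import pandas as pd
import pytest

from fjordsdm import projection, synthetic
from fjordsdm.covariates import COVARIATES, EnvStack
from fjordsdm.grids import RasterGrid
from fjordsdm.maxent import TrainingTable


@pytest.fixture(scope="session")
def small_world():
    """Two synthetic months on a 32x32 grid, shared across tests."""
    return projection.build_synthetic_world(
        ["2018-05", "2018-06"], shape=(32, 32), cell_size=500.0, seed=42, n_sightings=80
    )


@pytest.fixture(scope="session")
def month_table(small_world):
    """Training table (presences + effort-based absences) for one month."""
    return projection.month_training_table(small_world["2018-05"], seed=7)


@pytest.fixture()
def constant_stack():
    """A stack where every layer is constant (known extraction oracle)."""
    consts = {"sst": 5.0, "chlorophyll_a": 1.5, "salinity": 33.0,
              "depth": -40.0, "slope": 2.0, "dist_shore": 3000.0}
    layers = {
        name: RasterGrid(np.full((10, 10), c), 500.0, (0.0, 5000.0))
        for name, c in consts.items()
    }
    return EnvStack("2020-06", layers), consts


def labeled_table(X: np.ndarray, y: np.ndarray) -> TrainingTable:
    """Helper: wrap a (n, 6) covariate array and labels as a TrainingTable."""
    frame = pd.DataFrame(X, columns=list(COVARIATES))
    frame["label"] = y
    return TrainingTable(frame)
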