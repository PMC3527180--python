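import logging

import numpy as np
import pandas as pd
import pytest

from curvesample import ForestGrid, SimulationConfig
from curvesample import synthetic_data


@pytest.fixture(autouse=True)
def _quiet_extrapolation_warnings(caplog):
    # extrapolation warnings are tested explicitly where relevant
    logging.getLogger("curvesample.estimation").setLevel(logging.ERROR)
    yield
    logging.getLogger("curvesample.estimation").setLevel(logging.NOTSET)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def toy_training():
    """Two plots whose no-intercept quadratic fit is known in closed form."""
    return pd.DataFrame(
        {"plot_id": ["a", "b"], "lorey_height_m": [1.0, 2.0], "biomass_mg_ha": [2.0, 4.0]}
    )


@pytest.fixture
def full_grid_3x3():
    return ForestGrid(mask=np.ones((3, 3), dtype=bool), resolution=230.0)


@pytest.fixture(scope="session")
def small_config():
    """A fast, dense synthetic configuration for end-to-end tests."""
    return SimulationConfig(
        n_rows=40,
        n_cols=40,
        n_tracks=14,
        track_cluster_count=None,
        s2_size=20,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config, tmp_path_factory):
    """Synthetic mask/shots/training files written once per session."""
    outdir = tmp_path_factory.mktemp("simdata")
    paths = synthetic_data.write_simulation(outdir, small_config, seed=11)
    return paths
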