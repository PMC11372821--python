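import warnings

import numpy as np
import pytest

from tridacna_sdm.grid import GridSpec
from tridacna_sdm.pipeline import RunConfig, run
from tridacna_sdm.simulate import simulate_predictors

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", message=".*did not converge.*")
warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
warnings.filterwarnings("ignore", message=".*failed to converge.*")


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    """10° x 8° window at the working 5 arc-minute resolution."""
    return GridSpec(lon_min=100.0, lon_max=110.0, lat_min=-4.0, lat_max=4.0)


@pytest.fixture(scope="session")
def small_stack(small_grid):
    return simulate_predictors(small_grid, seed=5)


@pytest.fixture(scope="session")
def demo_ctx(tmp_path_factory):
    """One compact end-to-end pipeline run shared across tests.

    Small window and few CV replicates keep it quick while exercising every
    stage with all three modelling levels.
    """
    out = tmp_path_factory.mktemp("demo_run")
    cfg = RunConfig(
        out_dir=str(out),
        seed=1,
        n_presences=200,
        replicates=2,
        lon_min=110.0,
        lon_max=122.5,
        lat_min=-5.0,
        lat_max=5.0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
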