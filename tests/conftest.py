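import numpy as np
import pytest

from grassnpp import casa, potential, synthetic
from grassnpp.io_config import RunConfig


@pytest.fixture(scope="session")
def small_params():
    return synthetic.SimParams(n_rows=12, n_cols=12, seed=7)


@pytest.fixture(scope="session")
def sim_run(small_params):
    """One full synthetic pipeline run shared by read-only tests."""
    clim, ndvi = synthetic.simulate_inputs(small_params)
    cfg = RunConfig(years=small_params.years, seed=small_params.seed)
    act = casa.run_casa(clim.temperature, clim.precip, clim.solar, ndvi, cfg)
    np_ann, variant = potential.run_potential(clim.temperature, clim.precip, "auto")
    return {
        "params": small_params,
        "climate": clim,
        "ndvi": ndvi,
        "cfg": cfg,
        "actual": act,
        "np_annual": np_ann,
        "variant": variant,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
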