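import numpy as np
import pytest

from lakeshift.forcing import build_forcing
from lakeshift.grid import build_grid
from lakeshift.parameters import default_parameters
from lakeshift.physics import meteo_to_daily
from lakeshift.synthetic import (
    SyntheticLakeSpec, gen_hypsograph, gen_inflow, gen_meteorology,
)


@pytest.fixture(scope="session")
def lake_spec():
    return SyntheticLakeSpec()


@pytest.fixture(scope="session")
def hyps(lake_spec):
    return gen_hypsograph(lake_spec)


@pytest.fixture(scope="session")
def grid16(hyps):
    return build_grid(hyps, 16)


@pytest.fixture(scope="session")
def grid1(hyps):
    return build_grid(hyps, 1, zoom=0.0)


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def forcing_2yr(lake_spec):
    meteo = gen_meteorology(lake_spec, 2, seed=11)
    inflow = gen_inflow(lake_spec, 2, seed=12)
    return build_forcing(meteo_to_daily(meteo), inflow)


@pytest.fixture(scope="session")
def closed_forcing(forcing_2yr):
    """Closed-lake forcing: no inflow or outflow."""
    from dataclasses import replace

    f = forcing_2yr.tile(2)
    return replace(f, discharge=np.zeros(f.n_days))
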