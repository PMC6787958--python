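import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from adaptsample import (
    build_covariate_table,
    default_models,
    default_sites,
    predict_grid,
)
from adaptsample.covariates import Site


@pytest.fixture(scope="session")
def desert_site() -> Site:
    """A representative site in the default desert study area."""
    return Site("R01", 33.7, -115.4)


@pytest.fixture(scope="session")
def sites3():
    return default_sites(3, seed=5)


@pytest.fixture(scope="session")
def models():
    return default_models()


@pytest.fixture(scope="session")
def model_by_code(models):
    return {m.species_code: m for m in models}


@pytest.fixture(scope="session")
def march_cov(sites3):
    """Covariate table: 3 sites x March 2016."""
    dates = pd.date_range("2016-03-01", "2016-03-31", freq="D")
    return build_covariate_table(sites3, dates, seed=11)


@pytest.fixture(scope="session")
def march_grid(models, march_cov):
    """p_v grid for all nine species over the March covariates."""
    return predict_grid(models, march_cov)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
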