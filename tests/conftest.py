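import numpy as np
import pandas as pd
import pytest

from downwood import data_core
from downwood.data_core import COVARIATES, SpatialDataset


def make_dataset(n=20, seed=0, coords_scale=1000.0):
    """Small synthetic dataset with plausible covariate scales."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, coords_scale, size=(n, 2))
    X = pd.DataFrame({
        "NLT": rng.uniform(200, 3000, n),
        "canopy": rng.uniform(0.4, 0.9, n),
        "H": rng.uniform(2, 29, n),
        "slope": rng.uniform(2, 25, n),
        "DBH": rng.uniform(3, 48, n),
    })
    eta = -0.3 + 0.8 * (X["canopy"] - 0.65) / 0.1
    prob = 1 / (1 + np.exp(-eta))
    odw = rng.binomial(1, prob)
    ndw = rng.poisson(np.exp(1.5 + 0.5 * (X["DBH"] - 25) / 11))
    return SpatialDataset(unit_id=np.arange(n), coords=coords, X=X,
                          odw=odw, ndw=ndw)


@pytest.fixture
def small_ds():
    return make_dataset(n=40, seed=3)


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study with its ground truth (shared, read-only)."""
    from downwood import simulate
    return simulate.generate_default_study(1)


@pytest.fixture(scope="session")
def standardized_split(default_study):
    """355/88 split of the default study, standardized with training params."""
    ds, truth = default_study
    train, val = data_core.split_train_validation(ds, 355, seed=1)
    train_std, params = data_core.standardize(train)
    val_std, _ = data_core.standardize(val, params)
    return train, val, train_std, val_std, params, truth
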