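import numpy as np
import pandas as pd
import pytest

from sleephmm.model import HMMParameters


def random_parameters(rng: np.random.Generator) -> HMMParameters:
    """Random valid two-state parameters for property tests."""
    pi = rng.dirichlet([1.0, 1.0])
    transmat = np.stack([rng.dirichlet([5.0, 1.0]), rng.dirichlet([1.0, 5.0])])
    return HMMParameters(
        pi=pi,
        transmat=transmat,
        mu_hr=rng.uniform(50, 120, 2),
        sigma2_hr=rng.uniform(20, 300, 2),
        mu_act=rng.uniform(0, 3, 2),
        sigma2_act=rng.uniform(0.05, 1.5, 2),
        rho=rng.uniform(-0.8, 0.8, 2),
    )


def random_observations(rng, T, missing="none"):
    """Random bivariate observations with an optional missingness pattern."""
    hr = rng.uniform(40, 140, T)
    act = rng.uniform(0, 4, T)
    if missing == "some":
        hr[rng.random(T) < 0.3] = np.nan
        act[rng.random(T) < 0.2] = np.nan
    elif missing == "all":
        hr[:] = np.nan
        act[:] = np.nan
    return hr, act


@pytest.fixture
def rng():
    return np.random.default_rng(20180101)


@pytest.fixture
def separated_params():
    """Well-separated sleep (state 0) / wake (state 1) parameters."""
    return HMMParameters(
        pi=np.array([0.5, 0.5]),
        transmat=np.array([[0.98, 0.02], [0.01, 0.99]]),
        mu_hr=np.array([60.0, 95.0]),
        sigma2_hr=np.array([40.0, 150.0]),
        mu_act=np.array([0.1, 2.5]),
        sigma2_act=np.array([0.05, 1.0]),
        rho=np.array([0.0, 0.5]),
    )


def minute_index(n, start="2018-01-01 00:00"):
    return pd.date_range(start, periods=n, freq="min")
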