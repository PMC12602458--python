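import numpy as np
import pandas as pd
import pytest

from lagrisk import (
    AnalysisConfig,
    ScenarioConfig,
    TrueSurface,
    gen_environment,
    gen_outcomes,
    merge_panels,
)
from lagrisk.design import DesignMatrix


@pytest.fixture(scope="session")
def small_scenario():
    return ScenarioConfig(seed=20160101, n_districts=4, n_days=731)


@pytest.fixture(scope="session")
def small_panel(small_scenario):
    """Merged 4-district, 2-year panel with a linear PM2.5 effect."""
    env, districts = gen_environment(small_scenario)
    truth = TrueSurface.linear({"pm25": 0.003}, lag_weights=(0.5, 0.5))
    outcome = gen_outcomes(env, truth, small_scenario)
    return merge_panels(env, outcome), districts


@pytest.fixture(scope="session")
def null_panel():
    """Merged 4-district panel with no true pollutant effect."""
    cfg = ScenarioConfig(seed=42, n_districts=4, n_days=731)
    env, districts = gen_environment(cfg)
    outcome = gen_outcomes(env, TrueSurface.null(), cfg)
    return merge_panels(env, outcome), districts


@pytest.fixture
def fast_config():
    """Analysis config without the heavy temperature crossbasis."""
    return AnalysisConfig(
        pollutant="pm25", include_temperature=False, include_humidity=False
    )


def make_stratified_design(seed=1, n=500, n_strata=40, k=3, beta=(0.1, -0.2, 0.05),
                           dispersion=None):
    """Poisson panel with known coefficients and stratum intercepts."""
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, n_strata, n)
    X = rng.standard_normal((n, k))
    alpha = rng.normal(0.5, 0.5, n_strata)
    beta = np.asarray(beta, float)[:k]
    mu = np.exp(alpha[codes] + X @ beta)
    if dispersion is None:
        y = rng.poisson(mu)
    else:
        # gamma mixing with variance dispersion*mu requires shape mu/(phi-1)
        shape = mu / (dispersion - 1.0)
        y = rng.poisson(rng.gamma(shape, (dispersion - 1.0)))
    design = DesignMatrix(
        y=y.astype(float),
        X=X,
        strata=np.array([f"s{c:03d}" for c in codes]),
        column_map={"pollutant": slice(0, k)},
        index=pd.RangeIndex(n),
    )
    return design, beta, mu
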