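import numpy as np
import pytest

from somkin import ml
from somkin.kinetics import PoolKinetics
from somkin.synthetic import (SyntheticConfig, gen_covariates,
                              true_parameter_map)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_sites=300)


@pytest.fixture(scope="session")
def covariates_300(small_config):
    return gen_covariates(small_config, seed=42)


@pytest.fixture(scope="session")
def k3_training_data(small_config, covariates_300):
    """Covariates plus the pH-dominated passive-pool rate target."""
    y = true_parameter_map(covariates_300, small_config,
                           seed=7)["k3"].to_numpy()
    return covariates_300[ml.COVARIATES], y


@pytest.fixture(scope="session")
def fitted_rf(k3_training_data):
    """One RF model fitted once and shared across read-only tests."""
    X, y = k3_training_data
    return ml.train_model(X, y, method="rf", target_name="M3_k3", rfe=False,
                          seed=0, cv_folds=3, cv_repeats=1,
                          grid={"max_features": [4]})


@pytest.fixture
def three_pool_params():
    return PoolKinetics(f=[0.2, 0.3, 0.5], k=[0.05, 0.005, 0.0005], s0=1.0)


def random_pool_params(rng, n_pools=3, min_ratio=10.0):
    """Random kinetics with adjacent-pool rate ratios >= min_ratio."""
    k = [10 ** rng.uniform(-1.5, -0.5)]
    for _ in range(n_pools - 1):
        k.append(k[-1] / rng.uniform(min_ratio, 3 * min_ratio))
    f = rng.dirichlet(np.full(n_pools, 2.0)) * 0.85 + 0.15 / n_pools
    f = f / f.sum()
    return PoolKinetics(f=f, k=np.array(k), s0=1.0)
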