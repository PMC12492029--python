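import logging

import numpy as np
import pytest

from fermbed.design_space import default_design_space
from fermbed.gp import GPFitConfig, fit_gp

# campaign range warnings are expected all over the synthetic data
logging.getLogger("fermbed").setLevel(logging.ERROR)

MID_MEDIUM = np.array([100.0, 20.0, 5.0, 40.0, 15.0])  # suc, amm, pho, nit, start FM


@pytest.fixture(scope="session")
def space():
    return default_design_space()


@pytest.fixture(scope="session")
def mid_medium():
    return MID_MEDIUM.copy()


@pytest.fixture(scope="session")
def noise_floor_models():
    """Two small GPs fitted at the noise floor on a smooth bi-objective toy."""
    rng = np.random.default_rng(5)
    X = rng.random((12, 2))
    f1 = 2 + 2 * X[:, 0]
    f2 = 2 + 2 * (1 - X[:, 0]) * X[:, 1]
    m1 = fit_gp(X, f1, GPFitConfig(fixed_noise=1e-6, seed=0, restarts=4))
    m2 = fit_gp(X, f2, GPFitConfig(fixed_noise=1e-6, seed=0, restarts=4))
    return (m1, m2), X, np.c_[f1, f2]
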