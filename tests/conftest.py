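import logging

import numpy as np
import pytest
from scipy.special import expit

import miselect as ms

logging.getLogger("miselect").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def mech_one():
    return ms.build_mechanism("one")


@pytest.fixture(scope="session")
def mech_two():
    return ms.build_mechanism("two")


def make_logit_data(n=200, p=10, n_signal=4, seed=0, intercept=0.3):
    """Small logistic-regression dataset with known sparse coefficients."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    beta[:n_signal] = [1.0, -1.0, 0.5, 0.5][:n_signal]
    y = (rng.random(n) < expit(intercept + X @ beta)).astype(float)
    return X, y, beta


@pytest.fixture()
def logit_data():
    return make_logit_data()


@pytest.fixture(scope="session")
def small_imps(mech_one):
    """One small imputed scenario dataset reused across selector tests."""
    rng = np.random.default_rng(42)
    full = ms.generate_complete(mech_one, 250, rng)
    inc = ms.impose_mar(full, mech_one, 0.3, rng)
    return ms.impute(inc, m=5, rng=rng)


@pytest.fixture(scope="session")
def complete_imps(mech_one):
    """An 'imputation set' from fully observed data: m identical copies."""
    rng = np.random.default_rng(7)
    full = ms.generate_complete(mech_one, 300, rng)
    inc = ms.IncompleteDataset(
        X=full.X.copy(), y=full.y.copy(), R=np.zeros(full.X.shape, dtype=bool)
    )
    return ms.impute(inc, m=3, rng=rng)
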