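import numpy as np
import pandas as pd
import pytest

from tdcm.gibbs_engine import TDCMModel
from tdcm.model_core import ItemParams, QMatrix, ResponseData, TransitionParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_model():
    """K=1, T=2, J=2, I=4: small enough for exhaustive enumeration."""
    Q = QMatrix([[1], [1]])
    return TDCMModel.build(Q, T=2, n_respondents=4)


def make_intercept_only_model(K: int, T: int, J: int, I: int) -> TDCMModel:
    q = np.zeros((J, K), dtype=int)
    for j in range(J):
        q[j, j % K] = 1
    return TDCMModel.build(QMatrix(q), T=T, n_respondents=I)


def constant_gamma(model, values_by_type) -> TransitionParams:
    """Intercept-only coefficients with the given per-type intercepts."""
    gamma = TransitionParams.zeros(model.transition_design)
    for (k, r), v in gamma.gamma.items():
        v[0] = values_by_type.get(r, 0.0)
    return gamma


def flat_lambda(model) -> ItemParams:
    return ItemParams([np.zeros(dj.n_params) for dj in model.item_designs], False)
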