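import numpy as np
import pytest

from abckit import LinearGaussianModel, NormalMeanModel, PriorSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_prior():
    return [PriorSpec("mu", "uniform", (-5.0, 5.0))]


@pytest.fixture
def normal_mean_model():
    return NormalMeanModel(n_obs=10, sd=1.0)


@pytest.fixture
def linear_gaussian_1d():
    # 1 parameter, 1 statistic: s = 0.5 + 2*theta + eps, sd(eps) = 2
    return LinearGaussianModel([0.5], [[2.0]], [[4.0]])
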