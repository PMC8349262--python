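import numpy as np
import pytest

from kwstress import ModelParams, Thresholds, TwoSampleData, kw_sample

# the two parameter sets used throughout the Monte Carlo study
THETA_1 = ModelParams(alpha=5.0, beta1=3.5, beta2=3.25)
THETA_2 = ModelParams(alpha=1.25, beta1=7.0, beta2=4.2)
THRESH = Thresholds(a=0.1, b=0.2)
TRUE_R1 = 0.480959271
TRUE_R2 = 0.20582159557


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def scenario1_data():
    """A moderately sized sample pair from the first study scenario."""
    x = kw_sample(100, THETA_1.x_params, seed=101)
    y = kw_sample(100, THETA_1.y_params, seed=102)
    return TwoSampleData(x, y)


@pytest.fixture
def small_data():
    x = kw_sample(20, THETA_1.x_params, seed=201)
    y = kw_sample(25, THETA_1.y_params, seed=202)
    return TwoSampleData(x, y)


def random_theta(rng, lo=0.5, hi=8.0) -> ModelParams:
    a, b1, b2 = rng.uniform(lo, hi, size=3)
    return ModelParams(a, b1, b2)


def random_thresholds(rng) -> Thresholds:
    a, b = rng.uniform(0.0, 0.9, size=2)
    return Thresholds(a, b)
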