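import numpy as np
import pytest

from epibim import EpidemicParams, builtin_rates


@pytest.fixture
def eq46_params():
    """SIS study parameters: 4-week infective period, R0 = 0.15 < 1."""
    return EpidemicParams(alpha=13, beta=0.02, gamma=13, mu=0.013, K=200)


@pytest.fixture
def endemic_sis_params():
    """SIS study parameters with R0 = 1.38 > 1 (endemic regime)."""
    return EpidemicParams(alpha=52, beta=0.03, gamma=13, mu=0.013, K=3000)


@pytest.fixture
def endemic_sir_params():
    """SIR study parameters with R0 = 2.56 > 1 (endemic regime)."""
    return EpidemicParams(alpha=13, beta=0.1, gamma=26, mu=0.013, K=1000)


@pytest.fixture
def small_params():
    """Small-magnitude parameters whose stability constants stay representable."""
    return EpidemicParams(alpha=0.2, beta=0.1, gamma=0.1, mu=0.1, K=1.0)


@pytest.fixture
def const_rates(eq46_params):
    return builtin_rates("constant", eq46_params, c1=0.01, c2=0.01)


def random_states(rng, n, model, K, frac_zero_i=0.1):
    """Uniformly random interior states of the prism/triangle, some with I=0."""
    d = 3 if model == "sir" else 2
    w = rng.dirichlet(np.ones(d + 1), size=n)[:, :d] * K  # components a.s. > 0
    zero = rng.random(n) < frac_zero_i
    w[zero, 1] = 0.0
    return w
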