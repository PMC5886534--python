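import numpy as np
import pytest

from optstrat import (
    StratificationProblem,
    uniform,
    weibull3p,
)


@pytest.fixture
def uniform_problem():
    """Single uniform(0,1) auxiliary, unit coefficient, no error term."""
    return StratificationProblem.linear(
        0.0, 1.0, [uniform(0, 1)], [1.0], error_scale=None, L=2, grid_step=0.001
    )


@pytest.fixture
def weibull_problem():
    """Rayleigh-shaped Weibull auxiliary on [0, 4], no error term."""
    return StratificationProblem.linear(
        0.0, 4.0, [weibull3p(2.0, 1.0, 0.0)], [1.0], error_scale=None, L=3, grid_step=0.002
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20180405)
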