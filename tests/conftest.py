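import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import trapvol as tv

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ball():
    """Unit ball area function f(x) = pi(1 - x^2), the 1-oriented benchmark."""
    return tv.ball_area_function(1.0)


@pytest.fixture(scope="session")
def half_ball(ball):
    """Unit ball truncated at the equator: a 0-oriented object with a jump pi."""
    return tv.truncate_area_function(ball, 0.0)


@pytest.fixture
def toy_series():
    """Positions (0,1,2,4), areas (0,2,3,0): gaps (1,1,2), hand-checkable."""
    return tv.SectionSeries(np.array([0.0, 1.0, 2.0, 4.0]), np.array([0.0, 2.0, 3.0, 0.0]))


@pytest.fixture
def equidistant_series():
    """Positions (0,1,2,3), areas (0,2,3,0): constant gap 1."""
    return tv.SectionSeries(np.array([0.0, 1.0, 2.0, 3.0]), np.array([0.0, 2.0, 3.0, 0.0]))
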