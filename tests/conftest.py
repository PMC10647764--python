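import numpy as np
import pytest

from nucleokinetics import KineticParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def paper_scale_draw(rng):
    """Random (Q, S, theta) draws spanning the experimental concentration range.

    Q in [0.2, 5.5]e-7 M, S near the 601 template's 5.09e-7 M, theta such
    that |Q-S|*theta spans both the linear and the saturating regime.
    """
    def draw(n=100):
        Q = rng.uniform(0.2e-7, 5.5e-7, n)
        S = rng.uniform(3e-7, 7e-7, n)
        th = 10 ** rng.uniform(4.5, 7.0, n)
        return Q, S, th
    return draw


@pytest.fixture
def identity_params():
    """theta(T) = T: kbar=1, alpha=0, eps=1."""
    return KineticParams(kbar=1.0, alpha=0.0, eps=1.0)
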