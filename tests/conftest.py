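import numpy as np
import pytest

from piaf import ControlSpec, JointBelief, SystemParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def scalar_params():
    """Stock world: w=1, sigma_s=2, no process noise."""
    return SystemParams(w=np.array([1.0]), sigma_s=2.0, sigma_p=0.0)


@pytest.fixture
def sin_spec():
    return ControlSpec(regime="sinusoidal", T=50, phi=0.7)


def random_belief(rng, D: int) -> JointBelief:
    """A random valid joint belief (strictly positive definite)."""
    M = rng.normal(size=(1 + D, 1 + D))
    P = M @ M.T + 0.05 * np.eye(1 + D)
    return JointBelief(
        mu_z=float(rng.normal()),
        mu_w=rng.normal(size=D),
        Sigma_zz=P[0, 0],
        Sigma_ww=P[1:, 1:],
        Sigma_zw=P[0, 1:],
    )
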