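import numpy as np
import pytest

from xinact import InactivationPolicy, SelectionScheme


@pytest.fixture(scope="session")
def msb_scheme() -> SelectionScheme:
    """Reference deleterious-variation scheme with weak symmetric mutation."""
    return SelectionScheme(
        mode="deleterious", s_f=0.2, s_m=0.2, h=0.25, u_f=1e-5, u_m=1e-5
    )


@pytest.fixture(scope="session")
def sa_scheme() -> SelectionScheme:
    """Reference sexually antagonistic scheme inside the polymorphism region."""
    return SelectionScheme(mode="sexually_antagonistic", s_f=0.2, t_m=0.2, h=0.25)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20130418)


def make_policy(scheme, xi_11, xi_12=None, **kw) -> InactivationPolicy:
    return InactivationPolicy.from_scheme(scheme, xi_11=xi_11, xi_12=xi_12, **kw)
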