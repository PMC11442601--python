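import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from pefros import (
    SampleProperties,
    default_geometry,
    default_protocol,
    load_network,
)


@pytest.fixture(scope="session")
def network():
    return load_network()


@pytest.fixture(scope="session")
def geometry():
    return default_geometry()


@pytest.fixture(scope="session")
def protocol():
    return default_protocol()


@pytest.fixture(scope="session")
def sample():
    return SampleProperties()


def rk4_integrate(rhs, y0, t_grid):
    """Fixed-step classical Runge-Kutta reference integrator.

    Independent oracle for cross-checking the stiff solver on small
    sub-networks at small dt.
    """
    y = np.array(y0, dtype=float)
    out = [y.copy()]
    for t0, t1 in zip(t_grid[:-1], t_grid[1:]):
        h = t1 - t0
        k1 = rhs(t0, y)
        k2 = rhs(t0 + h / 2, y + h / 2 * k1)
        k3 = rhs(t0 + h / 2, y + h / 2 * k2)
        k4 = rhs(t1, y + h * k3)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        out.append(y.copy())
    return np.array(out)
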