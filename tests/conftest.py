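import numpy as np
import pytest

from ringmt import (KernelParams, NetworkParams, RingGrid, StimulusSpec,
                    build_kernel, make_input)
from ringmt.grid import wrap_angle


@pytest.fixture(scope="session")
def grid404():
    return RingGrid(404)


@pytest.fixture(scope="session")
def grid202():
    return RingGrid(202)


@pytest.fixture(scope="session")
def low_inhibition_params():
    """Low-inhibition connectivity regime (narrow excitation)."""
    return KernelParams(alpha=0.0, beta=-10.0)


@pytest.fixture(scope="session")
def kernel404(grid404, low_inhibition_params):
    return build_kernel(low_inhibition_params, grid404)


@pytest.fixture(scope="session")
def kernel202(grid202, low_inhibition_params):
    return build_kernel(low_inhibition_params, grid202)


@pytest.fixture
def net_params():
    return NetworkParams()


def gaussian_bump(grid, center_rad, width_rad, amplitude=1.0):
    """Peak-normalized test bump on the ring (helper, not the stimulus code)."""
    d = wrap_angle(grid.theta - center_rad)
    return amplitude * np.exp(-0.5 * (d / width_rad) ** 2)


@pytest.fixture
def bump():
    return gaussian_bump


@pytest.fixture
def symmetric_stimulus():
    return StimulusSpec(va_direction=0.0, ps=120.0, pw=10.0)


@pytest.fixture
def zero_input(grid404, symmetric_stimulus):
    from ringmt.stimulus import InputProfile

    return InputProfile(spec=symmetric_stimulus, grid=grid404,
                        values=np.zeros(grid404.n))
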