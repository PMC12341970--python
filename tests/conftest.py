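import numpy as np
import pytest

from ecres import linear, stimulus


@pytest.fixture(scope="session")
def resonator_pair():
    """Linear resonators with distinct resonance frequencies, equal peaks."""
    p1 = linear.design_resonator(0.9, 12.0)
    p2 = linear.design_resonator(1.3, 12.0)
    return p1, p2


@pytest.fixture(scope="session")
def short_zap():
    """A fast ZAP for unit tests (full band, shorter sweep)."""
    return stimulus.ZapParams(
        f_lo=0.1, f_hi=4.0, t_max=50.0, amplitude=1.5, offset=1.5,
        n_precycles=2, dt=1e-3, phase0=np.pi,
    )


@pytest.fixture(scope="session")
def standard_zap():
    """The standard protocol: 0.1-4 Hz over 100 s, I_max = 3 nA."""
    return stimulus.current_zap(3.0, dt=1e-3)
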