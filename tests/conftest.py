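import numpy as np
import pytest

from angioqa import (
    DeconvolutionConfig,
    StandardInjection,
    TimeDensityCurve,
    convolve,
    gen_irf,
    standard_injection,
)

DT = 0.1
DURATION = 20.0


@pytest.fixture(scope="session")
def grid():
    """(dt, duration) of the well-conditioned reference grid."""
    return DT, DURATION


@pytest.fixture(scope="session")
def std_injection_cfg():
    return StandardInjection(dt=DT, duration=DURATION)


@pytest.fixture(scope="session")
def std_curve(std_injection_cfg):
    return standard_injection(std_injection_cfg)


@pytest.fixture(scope="session")
def exp_irf():
    """Well-conditioned exponential impulse response (transit 1.2 s, unit gain)."""
    return gen_irf("exponential", mtt_true=1.2, gain=1.0, dt=DT, duration=DURATION)


@pytest.fixture(scope="session")
def noiseless_pair(exp_irf):
    """(aif, dome) pair generated by the exact forward model."""
    aif = standard_injection(StandardInjection(t_d=0.3, alpha=3, beta=0.4, dt=DT, duration=DURATION))
    return aif, convolve(exp_irf, aif)


@pytest.fixture()
def raw_cfg():
    """Deconvolution without truncation, clamping or baseline handling."""
    return DeconvolutionConfig(truncation_fraction=0.0, regularize_negative_irf=False, n_baseline=0)


def make_curve(values, dt=1.0, t0=0.0):
    return TimeDensityCurve(np.asarray(values, float), dt=dt, t0=t0)
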