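import numpy as np
import pytest

from chemsync import CircuitParams, InputProgram, SwitchParams
from chemsync.metrics import PeakSet


@pytest.fixture
def program_4h():
    return InputProgram(4.0, 2.0, 500.0, 1.0, True, 48.0, 10.0)


@pytest.fixture
def program_10h():
    return InputProgram(10.0, 5.0, 500.0, 1.0, True, 70.0, 10.0)


@pytest.fixture
def quiet_circuit():
    """Circuit with no extrinsic heterogeneity or measurement noise."""
    return CircuitParams(extrinsic_cv=0.0, measurement_cv=0.0)


@pytest.fixture
def noiseless_switch():
    return SwitchParams(noise_sigma=0.0)


def make_peakset(times_min):
    """PeakSet from peak times only (unit heights/widths)."""
    t = np.sort(np.asarray(times_min, dtype=float))
    if t.size:
        t = t[np.r_[True, np.diff(t) > 1e-9]]
    ones = np.ones(len(t))
    return PeakSet(t, ones, ones, ones)
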