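import numpy as np
import pytest

from ironmap import phantom


@pytest.fixture(scope="session")
def noiseless_phantom():
    """A 64x64 lesion phantom with exact piecewise-constant parameters."""
    return phantom.make_phantom(
        (64, 64), lesion="LCX", mpio_delta_r2star=40.0, seed=7
    )


@pytest.fixture(scope="session")
def multi_echo_schedule():
    return phantom.AcquisitionSchedule(
        "multi_echo", phantom.IN_VIVO_MULTI_ECHO_TES_MS
    )


@pytest.fixture(scope="session")
def ir_schedule():
    return phantom.AcquisitionSchedule(
        "inversion_recovery", phantom.DEFAULT_IR_TIS_MS
    )


@pytest.fixture(scope="session")
def t2prep_schedule():
    return phantom.AcquisitionSchedule("t2_prep", phantom.T2PREP_TIMES_MS)


def ols_line_oracle(x, y):
    """Brute-force normal-equations OLS for one pixel (independent oracle)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    det = n * sxx - sx * sx
    slope = (n * sxy - sx * sy) / det
    intercept = (sy - slope * sx) / n
    return slope, intercept
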