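import numpy as np
import pytest

from headgait.timeseries import PoseSeries


@pytest.fixture
def rate():
    return 50.0


def make_series(t, x=None, y=None, z=None, yaw=None, rate=50.0, source="ar",
                mask=None, extras=None):
    """Build a PoseSeries with zero-filled defaults for untested channels."""
    t = np.asarray(t, dtype=float)
    zeros = np.zeros_like(t)
    return PoseSeries(
        t=t,
        x=zeros.copy() if x is None else np.asarray(x, dtype=float),
        y=zeros.copy() if y is None else np.asarray(y, dtype=float),
        z=zeros.copy() if z is None else np.asarray(z, dtype=float),
        yaw=zeros.copy() if yaw is None else np.asarray(yaw, dtype=float),
        rate=rate, source=source, missing_mask=mask,
        extras=extras or {},
    )


@pytest.fixture
def series_factory():
    return make_series
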