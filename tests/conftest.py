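import numpy as np
import pytest

from dimerstate.bursts import BinnedTrace, Burst


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trace(f_dd, f_da=None, f_aa=None, bin_width=1e-3, background=(0.0, 0.0, 0.0),
               threshold=(3, 3, 3)):
    """Build a BinnedTrace directly from count arrays (test helper)."""
    f_dd = np.asarray(f_dd, dtype=np.int64)
    z = np.zeros_like(f_dd)
    trace = BinnedTrace(
        bin_width,
        f_dd,
        z if f_da is None else np.asarray(f_da, dtype=np.int64),
        z if f_aa is None else np.asarray(f_aa, dtype=np.int64),
    )
    trace.background = np.asarray(background, dtype=float)
    trace.threshold = np.asarray(threshold, dtype=int)
    return trace


def make_burst(f_dd=0, f_da=0, f_aa=0):
    """A burst whose background-subtracted counts equal its raw counts."""
    return Burst(0, 0, f_dd, f_da, f_aa, float(f_dd), float(f_da), float(f_aa))


@pytest.fixture
def trace_factory():
    return make_trace


@pytest.fixture
def burst_factory():
    return make_burst
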