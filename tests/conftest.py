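import numpy as np
import pytest

from mousesong.contours import ContourTrace
from mousesong.fixtures import load_table1_fixture


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20160329)


def make_trace(times, freqs=None, amps=None, **kw):
    times = np.asarray(times, float)
    if freqs is None:
        freqs = np.full_like(times, 70.0)
    if amps is None:
        amps = np.full_like(times, -40.0)
    return ContourTrace(times, np.asarray(freqs, float),
                        np.asarray(amps, float), **kw)
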