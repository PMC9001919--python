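import numpy as np
import pytest

from thermotrace import AnnotatorConfig, ReferenceRange, Trace

#: 16-sample hand-traceable example (dt = 2 s, threshold 18, hysteresis 2):
#: one bout [1, 15), events upper@5 (30.0), lower@8 (27.5), upper@11 (31.0)
MICRO_TEMPS = [
    18.0, 19.0, 21.0, 24.0, 27.0, 30.0, 29.0, 28.0,
    27.5, 28.5, 30.5, 31.0, 29.5, 28.9, 27.0, 18.0,
]


def make_trace(temps, dt=2.0, **kwargs):
    temps = np.asarray(temps, dtype=float)
    return Trace(t=np.arange(len(temps)) * dt, temp=temps, dt=dt, **kwargs)


@pytest.fixture
def micro_trace():
    return make_trace(MICRO_TEMPS)


@pytest.fixture
def default_cfg():
    return AnnotatorConfig()


@pytest.fixture
def baseline_ref():
    return ReferenceRange(lower=29.1, upper=34.7)


def random_walk_trace(rng, n=None, step_sd=0.5, start=25.0, resolution=0.0625):
    """Quantized random-walk trace; plateaus and ties arise naturally."""
    if n is None:
        n = int(rng.integers(10, 400))
    temps = start + np.cumsum(rng.normal(0.0, step_sd, size=n))
    temps = np.round(temps / resolution) * resolution
    return make_trace(temps, resolution=resolution)
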