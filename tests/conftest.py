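import numpy as np
import pytest

from fallstats.trace_io import AccelTrace


def make_trace(ax, ay=None, az=None, fs=50.0, **meta) -> AccelTrace:
    """Build a trace from short component lists, broadcasting constants."""
    ax = np.atleast_1d(np.asarray(ax, dtype=float))
    n = ax.shape[0]
    if ay is None:
        ay = np.zeros(n)
    if az is None:
        az = np.ones(n)
    ay = np.broadcast_to(np.asarray(ay, dtype=float), (n,)).copy()
    az = np.broadcast_to(np.asarray(az, dtype=float), (n,)).copy()
    meta.setdefault("activity_label", "walking")
    return AccelTrace(ax=ax, ay=ay, az=az, fs=fs, **meta)


def random_trace(rng, n, fs=50.0, scale=2.0) -> AccelTrace:
    comp = rng.normal(0.0, scale, (n, 3))
    comp[:, 2] += 1.0
    return AccelTrace(
        ax=comp[:, 0], ay=comp[:, 1], az=comp[:, 2], fs=fs,
        activity_label="walking",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
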