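import ctypes

import numpy as np
import pytest

from minicox import SurvivalDataset

# keep large array buffers on the heap for reuse across training steps
# (the simulation reproductions otherwise spend ~25% of their time in
# page faults re-mapping freed convolution buffers); best-effort
try:
    _libc = ctypes.CDLL("libc.so.6", use_errno=True)
    _libc.mallopt(-3, 512 * 1024 * 1024)  # M_MMAP_THRESHOLD
    _libc.mallopt(-1, -1)                 # M_TRIM_THRESHOLD
except OSError:
    pass


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_dataset(rng, n, censor_frac=0.3, with_labels=False, tie_prob=0.0):
    """A small random right-censored dataset for property tests."""
    times = rng.exponential(1.0, n) + 1e-3
    if tie_prob > 0.0:
        # force some exact ties by rounding a subset
        mask = rng.random(n) < tie_prob
        times[mask] = np.round(times[mask], 1) + 0.05
    events = (rng.random(n) >= censor_frac).astype(int)
    if not events.any():
        events[rng.integers(n)] = 1
    labels = rng.integers(0, 2, n) if with_labels else None
    return SurvivalDataset(times, events, labels=labels)


@pytest.fixture
def two_sample_events():
    """Times [1, 2], both events — the canonical hand-worked fixture."""
    return SurvivalDataset([1.0, 2.0], [1, 1])
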