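import numpy as np
import pytest

import tonalctx as tx


@pytest.fixture(scope="session")
def complex_600_800_1000():
    """1 s harmonic complex with a missing 200 Hz fundamental."""
    return tx.synth_complex_tone([600, 800, 1000], duration=1.0)


@pytest.fixture(scope="session")
def complex_series(complex_600_800_1000):
    return tx.pitch_series(complex_600_800_1000)


@pytest.fixture(scope="session")
def beating_pair():
    """1 s of 990 + 1100 Hz: within a critical band, beating at 110 Hz."""
    return tx.synth_complex_tone([990, 1100], duration=1.0)


@pytest.fixture(scope="session")
def beating_ani(beating_pair):
    return tx.ani(beating_pair)


def steady_frame(series, t=0.5):
    """A frame index well inside the steady state of a 1 s stimulus."""
    return int(np.argmin(np.abs(series.times - t)))
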