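import numpy as np
import pytest

from fmtheta.sim_subject import MONTAGE, SubjectModel, SubjectStream
from fmtheta.stream_chain import EEGChunk


@pytest.fixture(scope="session")
def quiet_subject():
    """A subject with no artifacts, for clean-signal tests."""
    return SubjectModel(sample_rate=256.0, blink_rate=0.0, muscle_rate=0.0,
                        rng_seed=11)


@pytest.fixture(scope="session")
def calibration_and_continuation(quiet_subject):
    """40 s calibration baseline plus a statistically identical 20 s
    continuation from the same stream."""
    stream = SubjectStream(quiet_subject)
    base, _ = stream.next_chunk(40.0)
    cont, _ = stream.next_chunk(20.0)
    return (EEGChunk(base, 256.0, MONTAGE), cont)


def sine_window(freq: float, amp: float = 1.0, n: int = 256,
                fs: float = 256.0, phase: float = 0.0) -> np.ndarray:
    t = np.arange(n) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)
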