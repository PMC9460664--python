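import numpy as np
import pytest

from eegscrub import Signal


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tone():
    """Cosine at normalized frequency 0.1, length 1024."""
    t = np.arange(1024)
    return Signal(np.cos(2 * np.pi * 0.1 * t), fs=1.0)


@pytest.fixture
def two_tone():
    """Sum of cosines at normalized frequencies 0.05 and 0.25, length 1024."""
    t = np.arange(1024)
    return Signal(
        np.cos(2 * np.pi * 0.05 * t) + np.cos(2 * np.pi * 0.25 * t), fs=1.0
    )


def periodogram_peak(x: np.ndarray) -> float:
    """Independent oracle: normalized frequency of the periodogram argmax."""
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size)
    return float(freqs[np.argmax(spec)])


def band_energy(x: np.ndarray, lo: float, hi: float) -> float:
    """Periodogram energy in a normalized-frequency band."""
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size)
    return float(spec[(freqs >= lo) & (freqs <= hi)].sum())
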