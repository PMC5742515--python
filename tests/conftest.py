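import numpy as np
import pytest
from scipy.signal import butter, sosfiltfilt

from imfcc.io import DEFAULT_CHANNELS, EegRecord, Frame


def eeg_like_signal(rng: np.random.Generator, n: int = 250,
                    fs: float = 250.0) -> np.ndarray:
    """Broadband EEG-like trace: several band-limited noise rhythms."""
    x = np.zeros(n)
    for lo, hi, amp in ((4, 7, 0.8), (8, 13, 1.0), (14, 30, 0.7),
                        (30, 60, 0.4)):
        sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        w = sosfiltfilt(sos, rng.standard_normal(n + 500))[250:-250]
        x += amp * w / np.std(w)
    return x


def make_frame(signal: np.ndarray, fs: float = 250.0,
               task: str | None = None) -> Frame:
    signal = np.atleast_2d(signal)
    labels = DEFAULT_CHANNELS[: signal.shape[0]] if signal.shape[0] <= 6 else \
        tuple(f"ch{i}" for i in range(signal.shape[0]))
    return Frame(signal=signal, fs=fs, channel_labels=labels, task=task)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def six_channel_record(rng) -> EegRecord:
    """10-s six-channel broadband session at 250 Hz."""
    sig = np.vstack([eeg_like_signal(rng, 2500) for _ in range(6)])
    return EegRecord(signal=sig, fs=250.0, channel_labels=DEFAULT_CHANNELS,
                     task="R", session_id="fixture")


@pytest.fixture
def noise_frame(rng) -> Frame:
    """Six channels of white noise: decomposes into many IMFs."""
    return make_frame(rng.standard_normal((6, 250)), task="R")


@pytest.fixture
def eeg_frame(rng) -> Frame:
    """Six channels of broadband EEG-like signal."""
    sig = np.vstack([eeg_like_signal(rng) for _ in range(6)])
    return make_frame(sig, task="M")
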