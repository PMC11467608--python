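import numpy as np
import pytest

from ocochew.data_model import CHANNEL_NAMES, AnnotationTrack, OcoRecording
from ocochew.preprocess import WindowSet, fft_features


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240926)


@pytest.fixture()
def zero_recording():
    return OcoRecording(participant_id="Z", sample_rate_hz=50.0, data=np.zeros((500, 8)))


def make_window_set(
    n_per_class: int = 40,
    window_len: int = 32,
    n_channels: int = 4,
    sample_rate_hz: float = 8.0,
    seed: int = 0,
    separation: float = 4.0,
) -> WindowSet:
    """Amplitude-coded, linearly separable two-class window set."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    labels = np.repeat([0, 1], n_per_class)
    windows = rng.normal(0.0, 1.0, size=(n, window_len, n_channels))
    t = np.arange(window_len) / sample_rate_hz
    windows[labels == 1] += separation * np.sin(2 * np.pi * 1.5 * t)[None, :, None]
    return WindowSet(
        windows=windows,
        freq=fft_features(windows),
        labels=labels,
        window_start_s=np.arange(n, dtype=float),
        window_s=window_len / sample_rate_hz,
        slide_s=1.0,
        sample_rate_hz=sample_rate_hz,
        channel_names=tuple(CHANNEL_NAMES[:n_channels]),
    )


@pytest.fixture()
def toy_window_set():
    return make_window_set(seed=1)


@pytest.fixture()
def toy_val_set():
    return make_window_set(n_per_class=15, seed=2)


@pytest.fixture()
def eating_track():
    return AnnotationTrack(intervals=[("eating", 10.0, 40.0)])
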