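"""Signal preprocessing for the statistics and detection chains.

Statistics chain: per-sensor vector magnitude -> left+right combination per
region -> rolling-median smoothing (15 samples = 0.3 s at 50 Hz).

Detection chain: kernel-5 median filter per channel -> partially overlapping
fixed-length windows (default 4 s window, 1 s slide) -> per-channel one-sided
FFT magnitude features alongside the time-domain tensors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .data_model import (
    CHANNEL_ORDER,
    AnnotationTrack,
    Axis,
    OcoRecording,
    Sensor,
    SensorChannel,
)
from .errors import ConfigError, DataError

__all__ = [
    "WindowSet",
    "median_filter_k",
    "vector_magnitude",
    "combine_left_right",
    "rolling_median_smooth",
    "region_magnitude_signals",
    "sensor_subset",
    "SENSOR_SUBSETS",
    "segment_windows",
    "fft_features",
    "concat_window_sets",
]

CHEWING, NONCHEWING = 1, 0

#: named sensor combinations from the sensor-ablation experiments
SENSOR_SUBSETS: dict[str, tuple[Sensor, ...]] = {
    "temple": (Sensor.O_RT, Sensor.O_LT),
    "cheek": (Sensor.O_RC, Sensor.O_LC),
    "temple+cheek": (Sensor.O_RC, Sensor.O_LC, Sensor.O_RT, Sensor.O_LT),
    "left": (Sensor.O_LC, Sensor.O_LT),
    "right": (Sensor.O_RC, Sensor.O_RT),
}


def sensor_subset(name: str) -> tuple[Sensor, ...]:
    try:
        return SENSOR_SUBSETS[name]
    except KeyError:
        raise ConfigError(
            f"unknown sensor subset {name!r}; choose from {sorted(SENSOR_SUBSETS)}"
        ) from None


@dataclass
class WindowSet:
    """Segmented, filtered windows with frequency features and labels.

    ``windows``: (n_windows, window_len_samples, n_channels) time-domain, mm.
    ``freq``: (n_windows, n_freq_bins, n_channels) one-sided FFT magnitudes
    (DC removed, unscaled; models apply their own 1/window_len scaling).
    ``labels``: 1 = chewing, 0 = nonchewing.
    """

    windows: np.ndarray
    freq: np.ndarray
    labels: np.ndarray
    window_start_s: np.ndarray
    window_s: float
    slide_s: float
    sample_rate_hz: float
    channel_names: tuple[str, ...]
    participant_ids: np.ndarray = field(default=None)  # per-window group id

    def __post_init__(self) -> None:
        if self.participant_ids is None:
            self.participant_ids = np.full(len(self.windows), "", dtype=object)

    def __len__(self) -> int:
        return self.windows.shape[0]

    @property
    def window_len_samples(self) -> int:
        return self.windows.shape[1]

    @property
    def n_channels(self) -> int:
        return self.windows.shape[2]

    @property
    def freq_bins_hz(self) -> np.ndarray:
        L = self.window_len_samples
        return np.fft.rfftfreq(L, d=1.0 / self.sample_rate_hz)[1 : L // 2 + 1]

    def subset(self, mask: np.ndarray) -> "WindowSet":
        return WindowSet(
            windows=self.windows[mask],
            freq=self.freq[mask],
            labels=self.labels[mask],
            window_start_s=self.window_start_s[mask],
            window_s=self.window_s,
            slide_s=self.slide_s,
            sample_rate_hz=self.sample_rate_hz,
            channel_names=self.channel_names,
            participant_ids=self.participant_ids[mask],
        )


def median_filter_k(signal: np.ndarray, k: int) -> np.ndarray:
    """Median filter with odd kernel ``k`` and reflect-padded edges."""
    signal = np.asarray(signal, dtype=float)
    if k % 2 == 0 or k < 1:
        raise ConfigError("median filter kernel must be odd and >= 1")
    if k > signal.shape[0]:
        raise ConfigError("kernel larger than signal")
    if k == 1:
        return signal.copy()
    return ndimage.median_filter(signal, size=k, mode="reflect")


def vector_magnitude(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Euclidean magnitude of the 2-D displacement, elementwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError(f"axis length mismatch: {x.shape} vs {y.shape}")
    return np.hypot(x, y)


def combine_left_right(left_mag: np.ndarray, right_mag: np.ndarray) -> np.ndarray:
    """Total regional movement: left + right sensor magnitudes."""
    left_mag = np.asarray(left_mag, dtype=float)
    right_mag = np.asarray(right_mag, dtype=float)
    if left_mag.shape != right_mag.shape:
        raise DataError("left/right length mismatch")
    return left_mag + right_mag


def rolling_median_smooth(signal: np.ndarray, window_samples: int = 15) -> np.ndarray:
    """Centered rolling median (reflect-padded), default 15 samples = 0.3 s."""
    if window_samples < 1:
        raise ConfigError("window_samples must be >= 1")
    signal = np.asarray(signal, dtype=float)
    return ndimage.median_filter(signal, size=window_samples, mode="reflect")


def region_magnitude_signals(
    rec: OcoRecording, smooth_samples: int = 15
) -> dict[str, np.ndarray]:
    """Statistics-chain signals: smoothed combined cheek and temple movement."""
    mags = {
        s: vector_magnitude(rec.channel(s, Axis.X), rec.channel(s, Axis.Y))
        for s in Sensor
    }
    return {
        "cheek": rolling_median_smooth(
            combine_left_right(mags[Sensor.O_LC], mags[Sensor.O_RC]), smooth_samples
        ),
        "temple": rolling_median_smooth(
            combine_left_right(mags[Sensor.O_LT], mags[Sensor.O_RT]), smooth_samples
        ),
    }


def fft_features(windows: np.ndarray) -> np.ndarray:
    """One-sided FFT magnitude per channel, DC removed.

    ``windows``: (n_windows, L, n_channels); returns (n_windows, L//2,
    n_channels) unscaled magnitudes (bin i corresponds to frequency
    (i+1) * fs / L).
    """
    if windows.size == 0:
        raise DataError("no windows")
    L = windows.shape[1]
    spec = np.abs(np.fft.rfft(windows, axis=1))[:, 1 : L // 2 + 1, :]
    return spec


def segment_windows(
    rec: OcoRecording,
    track: AnnotationTrack,
    window_s: float = 4.0,
    slide_s: float = 1.0,
    sensors: Sequence[Sensor] | str = "temple+cheek",
    median_k: int = 5,
    chewing_coverage: float = 0.5,
) -> WindowSet:
    """Median-filter selected channels and segment into labeled windows.

    A window is labeled chewing iff at least ``chewing_coverage`` of its
    samples fall inside eating-annotated intervals. The trailing partial
    window is dropped.
    """
    if isinstance(sensors, str):
        sensors = sensor_subset(sensors)
    if not sensors:
        raise ConfigError("sensor subset must be non-empty")
    fs = rec.sample_rate_hz
    L = int(round(window_s * fs))
    step = int(round(slide_s * fs))
    if step < 1:
        raise ConfigError("slide_s too small for the sample rate")
    if rec.n_samples < L:
        raise DataError("recording shorter than one window")

    channels = [
        SensorChannel(s, a) for s in CHANNEL_ORDER_SENSORS(sensors) for a in (Axis.X, Axis.Y)
    ]
    filtered = np.stack(
        [median_filter_k(rec.channel(c.sensor, c.axis), median_k) for c in channels],
        axis=1,
    )
    eating = np.zeros(rec.n_samples, dtype=bool)
    times = rec.times_s
    for s, e in track.eating_segments():
        eating |= (times >= s) & (times < e)

    n_windows = (rec.n_samples - L) // step + 1
    starts = np.arange(n_windows) * step
    windows = np.stack([filtered[i : i + L] for i in starts])
    labels = np.array(
        [CHEWING if eating[i : i + L].mean() >= chewing_coverage else NONCHEWING for i in starts]
    )
    ws = WindowSet(
        windows=windows,
        freq=fft_features(windows),
        labels=labels,
        window_start_s=rec.start_time + starts / fs,
        window_s=window_s,
        slide_s=slide_s,
        sample_rate_hz=fs,
        channel_names=tuple(c.name for c in channels),
        participant_ids=np.full(n_windows, rec.participant_id, dtype=object),
    )
    return ws


def CHANNEL_ORDER_SENSORS(sensors: Sequence[Sensor]) -> list[Sensor]:
    """Selected sensors in canonical order."""
    order = [c.sensor for c in CHANNEL_ORDER[::2]]
    chosen = set(sensors)
    return [s for s in order if s in chosen]


def concat_window_sets(sets: Iterable[WindowSet]) -> WindowSet:
    """Concatenate compatible WindowSets (e.g. across recordings)."""
    sets = list(sets)
    if not sets:
        raise DataError("no window sets to concatenate")
    first = sets[0]
    for ws in sets[1:]:
        if (
            ws.window_len_samples != first.window_len_samples
            or ws.n_channels != first.n_channels
            or ws.channel_names != first.channel_names
        ):
            raise DataError("incompatible window sets")
    return WindowSet(
        windows=np.concatenate([w.windows for w in sets]),
        freq=np.concatenate([w.freq for w in sets]),
        labels=np.concatenate([w.labels for w in sets]),
        window_start_s=np.concatenate([w.window_start_s for w in sets]),
        window_s=first.window_s,
        slide_s=first.slide_s,
        sample_rate_hz=first.sample_rate_hz,
        channel_names=first.channel_names,
        participant_ids=np.concatenate([w.participant_ids for w in sets]),
    )
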