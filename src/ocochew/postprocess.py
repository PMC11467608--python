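"""From window predictions to eating segments, chew counts and chewing rate.

A 2-state (noneating / eating) hidden Markov model with binary observations
(the hard window labels) is Viterbi-decoded to merge densely clustered
chewing predictions into coherent eating segments and suppress isolated
false positives. Transition persistence and emission probabilities are
estimated from training-fold statistics.

Within each detected segment the per-sensor magnitude signal with the
highest RMS is selected, median-filtered (kernel 5), band-passed to
0.5-3 Hz (zero-phase second-order Butterworth), and chews are counted as
peaks passing height, minimum-distance and prominence gates. The chewing
rate is the dominant spectral component of the same filtered signal in the
0.5-3 Hz band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .data_model import Axis, OcoRecording, Sensor
from .errors import ConfigError, DataError
from .models import WindowPredictions
from .preprocess import median_filter_k, vector_magnitude

__all__ = [
    "EatingSegment",
    "HmmParams",
    "estimate_hmm_params",
    "smooth_predictions",
    "extract_segments",
    "select_max_rms_channel",
    "count_chews",
    "estimate_chewing_rate",
    "analyze_segments",
]

NONEATING, EATING = 0, 1
CHEW_BAND_HZ = (0.5, 3.0)


@dataclass
class EatingSegment:
    start_s: float
    end_s: float
    n_windows: int
    chew_count: int | None = None
    chewing_rate_hz: float | None = None

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise DataError("segment end must follow start")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class HmmParams:
    """2-state HMM over binary chewing observations."""

    initial: tuple[float, float] = (0.99, 0.01)
    transition: tuple[tuple[float, float], tuple[float, float]] = (
        (0.98, 0.02),
        (0.05, 0.95),
    )
    #: per-state probability of observing a positive (chewing) window label
    emission_pos: tuple[float, float] = (0.05, 0.90)

    def __post_init__(self) -> None:
        for row in self.transition:
            if abs(sum(row) - 1.0) > 1e-9 or min(row) < 0:
                raise ConfigError("transition rows must be probability vectors")
        if abs(sum(self.initial) - 1.0) > 1e-9:
            raise ConfigError("initial distribution must sum to 1")
        if not all(0.0 < p < 1.0 for p in self.emission_pos):
            raise ConfigError("emission probabilities must lie in (0, 1)")


def _mean_run_length(labels: np.ndarray, value: int) -> float:
    runs = []
    count = 0
    for v in labels:
        if v == value:
            count += 1
        elif count:
            runs.append(count)
            count = 0
    if count:
        runs.append(count)
    return float(np.mean(runs)) if runs else 1.0


def estimate_hmm_params(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    min_emission: float = 0.01,
    min_persistence: float = 0.90,
) -> HmmParams:
    """Fix HMM parameters from training-fold label statistics.

    Persistence of each state is ``1 - 1/mean_run_length`` of the true label
    runs; emissions are the classifier's confusion rates (P(pred=1 | state)).
    Floors keep the chain persistence-dominant and emissions non-degenerate.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    persist = []
    for state in (NONEATING, EATING):
        mrl = _mean_run_length(y_true, state)
        persist.append(min(max(1.0 - 1.0 / max(mrl, 1.0 + 1e-9), min_persistence), 0.999))
    emis = []
    for state in (NONEATING, EATING):
        mask = y_true == state
        rate = float(y_pred[mask].mean()) if mask.any() else (0.5 if state else 0.05)
        emis.append(min(max(rate, min_emission), 1.0 - min_emission))
    p_eating = float((y_true == EATING).mean())
    p_eating = min(max(p_eating, 1e-3), 1.0 - 1e-3)
    return HmmParams(
        initial=(1.0 - p_eating, p_eating),
        transition=(
            (persist[0], 1.0 - persist[0]),
            (1.0 - persist[1], persist[1]),
        ),
        emission_pos=tuple(emis),
    )


def smooth_predictions(preds: WindowPredictions | np.ndarray, params: HmmParams) -> np.ndarray:
    """Viterbi-decode the most likely eating/noneating state sequence."""
    obs = preds.label if isinstance(preds, WindowPredictions) else np.asarray(preds)
    obs = obs.astype(int)
    if obs.size == 0:
        raise DataError("no predictions to smooth")
    log_init = np.log(np.asarray(params.initial))
    log_trans = np.log(np.asarray(params.transition))
    e_pos = np.asarray(params.emission_pos)
    log_emit = np.stack([np.log(1.0 - e_pos), np.log(e_pos)])  # (obs, state)

    n = obs.size
    delta = log_init + log_emit[obs[0]]
    back = np.zeros((n, 2), dtype=int)
    for t in range(1, n):
        cand = delta[:, None] + log_trans  # (from, to)
        back[t] = cand.argmax(axis=0)
        delta = cand.max(axis=0) + log_emit[obs[t]]
    states = np.zeros(n, dtype=int)
    states[-1] = int(delta.argmax())
    for t in range(n - 2, -1, -1):
        states[t] = back[t + 1, states[t + 1]]
    return states


def extract_segments(
    states: np.ndarray, window_start_s: np.ndarray, window_s: float
) -> list[EatingSegment]:
    """Maximal runs of eating-state windows as time segments.

    A segment spans from the first window's start to the last window's start
    plus the window length.
    """
    states = np.asarray(states).astype(int)
    segments: list[EatingSegment] = []
    start = None
    for i, s in enumerate(states):
        if s == EATING and start is None:
            start = i
        elif s != EATING and start is not None:
            segments.append(_segment(window_start_s, start, i - 1, window_s))
            start = None
    if start is not None:
        segments.append(_segment(window_start_s, start, len(states) - 1, window_s))
    return segments


def _segment(window_start_s: np.ndarray, i0: int, i1: int, window_s: float) -> EatingSegment:
    return EatingSegment(
        start_s=float(window_start_s[i0]),
        end_s=float(window_start_s[i1] + window_s),
        n_windows=i1 - i0 + 1,
    )


def select_max_rms_channel(
    rec: OcoRecording, segment: EatingSegment
) -> tuple[str, np.ndarray]:
    """Per-sensor magnitude with the highest RMS over the segment.

    Candidates are the four sensor magnitudes in canonical order (O_RC,
    O_LC, O_RT, O_LT); ties resolve to the earliest in that order.
    """
    fs = rec.sample_rate_hz
    i0 = int(round((segment.start_s - rec.start_time) * fs))
    i1 = int(round((segment.end_s - rec.start_time) * fs))
    i0, i1 = max(i0, 0), min(i1, rec.n_samples)
    if i1 - i0 < 1:
        raise DataError("segment does not overlap the recording")
    best_name, best_sig, best_rms = None, None, -1.0
    for sensor in (Sensor.O_RC, Sensor.O_LC, Sensor.O_RT, Sensor.O_LT):
        mag = vector_magnitude(
            rec.channel(sensor, Axis.X)[i0:i1], rec.channel(sensor, Axis.Y)[i0:i1]
        )
        rms = float(np.sqrt(np.mean(mag**2)))
        if rms > best_rms:
            best_name, best_sig, best_rms = sensor.value, mag, rms
    return best_name, best_sig


def _chew_filter(signal: np.ndarray, fs: float) -> np.ndarray:
    filtered = median_filter_k(signal, 5)
    nyq = fs / 2.0
    lo, hi = CHEW_BAND_HZ[0] / nyq, min(CHEW_BAND_HZ[1] / nyq, 0.99)
    b, a = sps.butter(2, (lo, hi), btype="bandpass")
    return sps.filtfilt(b, a, filtered)


def count_chews(
    signal: np.ndarray,
    sample_rate_hz: float,
    height_rms_factor: float = 0.3,
    prominence_median_factor: float = 0.5,
) -> tuple[int, np.ndarray]:
    """Count chews as prominent peaks of the filtered magnitude signal.

    Gates: minimum inter-peak distance fs/3 samples (3 chews/s ceiling),
    height >= ``height_rms_factor`` x filtered-signal RMS, prominence >=
    ``prominence_median_factor`` x median height of the retained peaks.
    Returns the count and peak times (s, relative to the signal start).
    """
    signal = np.asarray(signal, dtype=float)
    fs = sample_rate_hz
    if signal.size < 2 * fs:
        raise DataError("segment must span at least 2 s for chew counting")
    filtered = _chew_filter(signal, fs)
    rms = float(np.sqrt(np.mean(filtered**2)))
    if rms < 1e-9:  # mm; below any optical sensor's noise floor
        return 0, np.empty(0)
    distance = max(int(fs / CHEW_BAND_HZ[1]), 1)
    peaks, props = sps.find_peaks(filtered, height=height_rms_factor * rms, distance=distance)
    if peaks.size == 0:
        return 0, np.empty(0)
    prominences = sps.peak_prominences(filtered, peaks)[0]
    min_prom = prominence_median_factor * float(np.median(props["peak_heights"]))
    keep = prominences >= min_prom
    peaks = peaks[keep]
    return int(peaks.size), peaks / fs


def estimate_chewing_rate(
    signal: np.ndarray, sample_rate_hz: float, min_resolution_hz: float = 0.02
) -> float:
    """Dominant spectral component of the filtered signal in 0.5-3 Hz.

    The FFT is zero-padded so the bin spacing is at most
    ``min_resolution_hz``.
    """
    signal = np.asarray(signal, dtype=float)
    fs = sample_rate_hz
    if signal.size < 4 * fs:
        raise DataError("segment must span at least 4 s for rate estimation")
    filtered = _chew_filter(signal, fs)
    nfft = int(2 ** np.ceil(np.log2(max(filtered.size, fs / min_resolution_hz))))
    spec = np.abs(np.fft.rfft(filtered, n=nfft))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    band = (freqs >= CHEW_BAND_HZ[0]) & (freqs <= CHEW_BAND_HZ[1])
    if not band.any():
        raise DataError("no spectral bins inside the chewing band")
    return float(freqs[band][np.argmax(spec[band])])


def analyze_segments(
    rec: OcoRecording, segments: Sequence[EatingSegment]
) -> list[EatingSegment]:
    """Fill chew counts and chewing rates for detected segments in place."""
    for seg in segments:
        _, sig = select_max_rms_channel(rec, seg)
        if sig.size >= 2 * rec.sample_rate_hz:
            count, _ = count_chews(sig, rec.sample_rate_hz)
            seg.chew_count = count
        if sig.size >= 4 * rec.sample_rate_hz:
            seg.chewing_rate_hz = estimate_chewing_rate(sig, rec.sample_rate_hz)
    return list(segments)
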