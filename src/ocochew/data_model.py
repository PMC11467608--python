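"""Core domain types and CSV I/O for optomyography (OCO) recordings.

Smart glasses with OCO sensors track skin displacement over facial muscles
using optical surface-tracking. The four sensors relevant to eating are the
left/right cheek (zygomaticus region) and left/right temple (temporalis
region); each reports displacement along two axes (X, Y) in millimetres.

On-disk formats are plain CSV:

* recording: header ``time_s,O_RC_x,O_RC_y,O_LC_x,O_LC_y,O_RT_x,O_RT_y,O_LT_x,O_LT_y``
* annotations: header ``label,start_s,end_s`` with half-open intervals [start, end)
* chew events: header ``time_s``
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path


import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, FormatError

__all__ = [
    "Sensor",
    "Axis",
    "SensorChannel",
    "CHANNEL_ORDER",
    "CHANNEL_NAMES",
    "OcoRecording",
    "AnnotationTrack",
    "ChewEventTrack",
    "LABEL_VOCABULARY",
    "read_recording",
    "write_recording",
    "read_annotations",
    "write_annotations",
    "read_chew_events",
    "write_chew_events",
]


class Sensor(str, Enum):
    """The four OCO sensors used for eating detection."""

    O_RC = "O_RC"  # right cheek
    O_LC = "O_LC"  # left cheek
    O_RT = "O_RT"  # right temple
    O_LT = "O_LT"  # left temple


class Axis(str, Enum):
    X = "x"
    Y = "y"


@dataclass(frozen=True)
class SensorChannel:
    sensor: Sensor
    axis: Axis

    @property
    def name(self) -> str:
        return f"{self.sensor.value}_{self.axis.value}"


#: Canonical channel ordering: (O_RC.x, O_RC.y, O_LC.x, O_LC.y, O_RT.x, O_RT.y, O_LT.x, O_LT.y)
CHANNEL_ORDER: tuple[SensorChannel, ...] = tuple(
    SensorChannel(s, a) for s in (Sensor.O_RC, Sensor.O_LC, Sensor.O_RT, Sensor.O_LT) for a in (Axis.X, Axis.Y)
)
CHANNEL_NAMES: tuple[str, ...] = tuple(c.name for c in CHANNEL_ORDER)

LABEL_VOCABULARY = frozenset({"eating", "speaking", "clenching", "other", "none"})

#: sensors' stated accurate operating range implies a displacement plausibility bound
DEFAULT_MAX_ABS_MM = 30.0


@dataclass
class OcoRecording:
    """Uniformly sampled 8-channel skin-displacement time series (mm)."""

    participant_id: str
    sample_rate_hz: float
    data: np.ndarray  # (n_samples, 8)
    start_time: float = 0.0
    channel_index: tuple[SensorChannel, ...] = CHANNEL_ORDER

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.sample_rate_hz <= 0:
            raise ConfigError("sample_rate_hz must be positive")
        if self.data.ndim != 2 or self.data.shape[1] != len(self.channel_index):
            raise DataError(
                f"data must be (n_samples, {len(self.channel_index)}); got {self.data.shape}"
            )
        if self.data.shape[0] < 1:
            raise DataError("recording must contain at least one sample")
        if not np.isfinite(self.data).all():
            raise DataError("recording contains non-finite displacements")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sample_rate_hz

    def channel(self, sensor: Sensor, axis: Axis) -> np.ndarray:
        idx = self.channel_index.index(SensorChannel(sensor, axis))
        return self.data[:, idx]

    def validate_amplitude(self, max_abs_mm: float = DEFAULT_MAX_ABS_MM) -> None:
        if np.abs(self.data).max() > max_abs_mm:
            raise DataError(f"displacement exceeds plausibility bound {max_abs_mm} mm")


@dataclass
class AnnotationTrack:
    """Non-overlapping labeled half-open intervals [start_s, end_s)."""

    intervals: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ivs = [(str(l), float(s), float(e)) for l, s, e in self.intervals]
        for l, s, e in ivs:
            if not s < e:
                raise DataError(f"interval {l!r}: start {s} must precede end {e}")
        ivs.sort(key=lambda t: t[1])
        for (_, _, e0), (l1, s1, _) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise DataError(f"overlapping intervals at {s1} s (label {l1!r})")
        self.intervals = ivs

    def __len__(self) -> int:
        return len(self.intervals)

    def labels_for_samples(self, times_s: np.ndarray, default: str = "none") -> np.ndarray:
        """Per-sample activity label; samples outside any interval get ``default``."""
        out = np.full(len(times_s), default, dtype=object)
        for label, s, e in self.intervals:
            out[(times_s >= s) & (times_s < e)] = label
        return out

    def intervals_with_label(self, label: str) -> list[tuple[float, float]]:
        return [(s, e) for l, s, e in self.intervals if l == label]

    def eating_segments(self) -> list[tuple[float, float]]:
        """Eating segments: the continuous food-consumption intervals."""
        return self.intervals_with_label("eating")


@dataclass
class ChewEventTrack:
    """Timestamps (s) of individual masticatory cycles."""

    event_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        t = np.asarray(self.event_times_s, dtype=float)
        if t.size and not np.all(np.diff(t) > 0):
            raise DataError("chew event times must be strictly increasing")
        self.event_times_s = t

    def __len__(self) -> int:
        return int(self.event_times_s.size)

    def count_in(self, start_s: float, end_s: float) -> int:
        t = self.event_times_s
        return int(np.count_nonzero((t >= start_s) & (t < end_s)))


# ---------------------------------------------------------------------------
# I/O


def read_recording(
    path: str | Path,
    fmt: str = "csv",
    *,
    max_nan_fraction: float = 0.05,
    max_gap_s: float = 0.2,
    participant_id: str | None = None,
) -> OcoRecording:
    """Load a recording CSV.

    Missing values are tolerated up to ``max_nan_fraction`` per channel and
    linearly interpolated when each run of missing samples spans at most
    ``max_gap_s`` seconds; longer gaps are a data error (split the file
    upstream instead).
    """
    if fmt != "csv":
        raise ConfigError(f"unsupported format {fmt!r}")
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_s" not in df.columns:
        raise FormatError("recording CSV must contain a 'time_s' column")
    missing = [n for n in CHANNEL_NAMES if n not in df.columns]
    if missing:
        raise FormatError(f"recording CSV missing channel column(s): {', '.join(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 1:
        raise DataError("recording CSV has no samples")
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise DataError("time_s must be strictly increasing")
        sample_rate = 1.0 / float(np.median(dt))
    else:
        sample_rate = 50.0
    data = df[list(CHANNEL_NAMES)].to_numpy(dtype=float)
    nan_frac = np.isnan(data).mean(axis=0)
    if np.any(nan_frac > max_nan_fraction):
        bad = CHANNEL_NAMES[int(np.argmax(nan_frac))]
        raise DataError(f"channel {bad} has {nan_frac.max():.1%} missing values")
    data = _interpolate_gaps(data, sample_rate, max_gap_s)
    return OcoRecording(
        participant_id=participant_id or path.stem,
        sample_rate_hz=sample_rate,
        data=data,
        start_time=float(t[0]),
    )


def _interpolate_gaps(data: np.ndarray, sample_rate_hz: float, max_gap_s: float) -> np.ndarray:
    if not np.isnan(data).any():
        return data
    max_gap = int(round(max_gap_s * sample_rate_hz))
    out = data.copy()
    idx = np.arange(data.shape[0])
    for c in range(data.shape[1]):
        nan = np.isnan(out[:, c])
        if not nan.any():
            continue
        # check longest run of NaNs
        run = 0
        for v in nan:
            run = run + 1 if v else 0
            if run > max_gap:
                raise DataError(
                    f"missing-sample gap longer than {max_gap_s} s; split the recording"
                )
        if nan.all() or nan[0] or nan[-1]:
            raise DataError("missing samples at recording boundary cannot be interpolated")
        out[nan, c] = np.interp(idx[nan], idx[~nan], out[~nan, c])
    return out


def write_recording(rec: OcoRecording, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(rec.data, columns=list(CHANNEL_NAMES))
    df.insert(0, "time_s", rec.times_s)
    # default float formatting is shortest-round-trip, so values survive exactly
    df.to_csv(path, index=False)
    return path


def read_annotations(path: str | Path) -> AnnotationTrack:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("label", "start_s", "end_s"):
        if col not in df.columns:
            raise FormatError(f"annotation CSV missing column {col!r}")
    intervals = [
        (str(r.label), float(r.start_s), float(r.end_s)) for r in df.itertuples(index=False)
    ]
    return AnnotationTrack(intervals=intervals)


def write_annotations(track: AnnotationTrack, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(track.intervals, columns=["label", "start_s", "end_s"])
    df.to_csv(path, index=False)
    return path


def read_chew_events(path: str | Path) -> ChewEventTrack:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_s" not in df.columns:
        raise FormatError("chew-event CSV missing column 'time_s'")
    return ChewEventTrack(event_times_s=df["time_s"].to_numpy(dtype=float))


def write_chew_events(track: ChewEventTrack, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": track.event_times_s}).to_csv(path, index=False)
    return path
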