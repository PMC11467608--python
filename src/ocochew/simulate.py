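"""Synthetic optomyography cohort generator.

Emulates the statistical structure the detection method relies on, so the
whole pipeline is testable without access to glasses hardware:

* **eating** — bite-structured quasi-periodic oscillation: bursts of
  raised-cosine chew cycles at a per-bite rate drawn from 0.8-2.3 chews/s,
  separated by short pauses; cheek amplitude well above temple amplitude.
  Each chew cycle emits one ground-truth event time.
* **speaking** — irregular band-limited movement at a lower amplitude.
* **clenching** — near-static, very small slow displacement.
* **none / other** — sensor noise only, or weak irregular movement.

Per-activity amplitudes are calibrated so the *combined left+right* mean
magnitude during the activity hits the target (defaults: cheek
0.113/0.036/0.008 mm and temple 0.027/0.008/0.002 mm for
eating/speaking/clenching), with log-normal per-participant multipliers, so
a synthetic cohort reproduces the reported ordering of facial-activity
amplitudes (eating >> speaking >> clenching).
"""

from __future__ import annotations

from dataclasses import dataclass, replace


import numpy as np
from scipy import signal as sps

from .data_model import CHANNEL_ORDER, AnnotationTrack, ChewEventTrack, OcoRecording
from .errors import ConfigError

__all__ = [
    "ActivityModel",
    "CohortSpec",
    "CohortItem",
    "DEFAULT_ACTIVITY_MODELS",
    "default_lab_schedule",
    "default_detection_schedule",
    "default_lab_cohort_spec",
    "simulate_activity",
    "simulate_cohort",
    "simulate_chew_segment",
]

#: observed chewing-rate range, chews per second
DEFAULT_RATE_RANGE = (0.8, 2.3)

#: default per-axis additive sensor noise, mm
DEFAULT_NOISE_SD_MM = 0.001


@dataclass(frozen=True)
class ActivityModel:
    """Generative parameters for one activity label.

    ``cheek_amp_mm``/``temple_amp_mm`` are targets for the *mean combined
    left+right magnitude* during the activity, matching how the statistics
    chain summarises movement.
    """

    label: str
    cheek_amp_mm: float
    temple_amp_mm: float
    periodic: bool = False
    rate_range_hz: tuple[float, float] = DEFAULT_RATE_RANGE
    noise_sd_mm: float = DEFAULT_NOISE_SD_MM
    bandwidth_hz: float = 4.0  # band limit for non-periodic movement
    bite_len_chews: tuple[int, int] = (5, 20)
    pause_range_s: tuple[float, float] = (0.5, 3.0)
    chew_amp_jitter: float = 0.2

    def __post_init__(self) -> None:
        if self.cheek_amp_mm < 0 or self.temple_amp_mm < 0 or self.noise_sd_mm < 0:
            raise ConfigError(f"{self.label}: amplitudes and noise must be non-negative")
        lo, hi = self.rate_range_hz
        if self.periodic and not (0 < lo <= hi):
            raise ConfigError(f"{self.label}: invalid rate range {self.rate_range_hz}")
        if self.periodic and self.cheek_amp_mm <= self.temple_amp_mm and self.cheek_amp_mm > 0:
            raise ConfigError(f"{self.label}: chewing must be cheek-dominant")


DEFAULT_ACTIVITY_MODELS: dict[str, ActivityModel] = {
    "eating": ActivityModel("eating", 0.113, 0.027, periodic=True),
    "speaking": ActivityModel("speaking", 0.036, 0.008, bandwidth_hz=4.0),
    "clenching": ActivityModel("clenching", 0.008, 0.002, bandwidth_hz=0.3),
    "other": ActivityModel("other", 0.020, 0.006, bandwidth_hz=2.0),
    "none": ActivityModel("none", 0.0, 0.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Specification for a deterministic synthetic cohort."""

    n_participants: int
    schedule: tuple[tuple[str, float], ...]
    seed: int
    per_participant_amp_multiplier_sd: float = 0.35
    per_activity_jitter_sd: float = 0.10
    sample_rate_hz: float = 50.0
    activity_models: tuple[ActivityModel, ...] = tuple(DEFAULT_ACTIVITY_MODELS.values())

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ConfigError("cohort needs at least 2 participants")
        if any(d <= 0 for _, d in self.schedule):
            raise ConfigError("schedule durations must be positive")
        models = {m.label for m in self.activity_models}
        unknown = {l for l, _ in self.schedule} - models
        if unknown:
            raise ConfigError(f"schedule labels without an activity model: {unknown}")

    def model_for(self, label: str) -> ActivityModel:
        for m in self.activity_models:
            if m.label == label:
                return m
        raise ConfigError(f"no activity model for {label!r}")


@dataclass
class CohortItem:
    recording: OcoRecording
    annotations: AnnotationTrack
    chew_events: ChewEventTrack


def default_lab_schedule() -> tuple[tuple[str, float], ...]:
    """Laboratory-protocol-style block schedule (eat / speak / clench)."""
    return (
        ("none", 10.0),
        ("eating", 90.0),
        ("none", 5.0),
        ("speaking", 90.0),
        ("none", 5.0),
        ("clenching", 90.0),
        ("none", 10.0),
    )


def default_detection_schedule(total_s: float = 360.0) -> tuple[tuple[str, float], ...]:
    """Mixed-activity schedule for training/evaluating the detector."""
    base = (
        ("none", 20.0),
        ("eating", 60.0),
        ("speaking", 40.0),
        ("none", 10.0),
        ("eating", 50.0),
        ("clenching", 30.0),
        ("speaking", 30.0),
        ("none", 20.0),
        ("eating", 60.0),
        ("clenching", 20.0),
        ("none", 20.0),
    )
    scale = total_s / sum(d for _, d in base)
    return tuple((l, d * scale) for l, d in base)


def default_lab_cohort_spec(seed: int, n_participants: int = 28) -> CohortSpec:
    return CohortSpec(n_participants=n_participants, schedule=default_lab_schedule(), seed=seed)


# ---------------------------------------------------------------------------
# signal blocks


def _chew_magnitude(
    model: ActivityModel, duration_s: float, fs: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-scale chewing magnitude envelope and its chew-event times.

    Bites are bursts of raised-cosine cycles (one positive lobe per
    masticatory cycle) at a per-bite rate, separated by pauses; the trailing
    partial cycle is dropped.
    """
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    mag = np.zeros(n)
    events: list[float] = []
    cursor = 0.0
    lo, hi = model.rate_range_hz
    while cursor < duration_s:
        rate = rng.uniform(lo, hi)
        n_chews = int(rng.integers(model.bite_len_chews[0], model.bite_len_chews[1] + 1))
        for _ in range(n_chews):
            cycle_end = cursor + 1.0 / rate
            if cycle_end > duration_s + 1e-9:
                cursor = duration_s
                break
            sl = (t >= cursor) & (t < cycle_end)
            amp = 1.0 + model.chew_amp_jitter * rng.uniform(-1.0, 1.0)
            mag[sl] += amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * rate * (t[sl] - cursor)))
            events.append(cursor + 0.5 / rate)
            cursor = cycle_end
        else:
            p_lo, p_hi = model.pause_range_s
            cursor += rng.uniform(p_lo, p_hi) if p_hi > 0 else 0.0
            continue
        break
    return mag, np.asarray(events)


def _bandlimited_magnitude(
    bandwidth_hz: float, n: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Non-negative, band-limited irregular magnitude envelope (unit scale)."""
    white = rng.standard_normal(n + 2 * int(fs))
    wn = min(bandwidth_hz / (fs / 2.0), 0.99)
    b, a = sps.butter(4, wn)
    smooth = sps.filtfilt(b, a, white)[int(fs) : int(fs) + n]
    return np.abs(smooth)


def _project_xy(mag: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Split a magnitude envelope into X/Y with a random constant direction."""
    phi = rng.uniform(0.0, 2.0 * np.pi)
    return mag * np.cos(phi), mag * np.sin(phi)


def simulate_activity(
    model: ActivityModel,
    duration_s: float,
    rng: np.random.Generator,
    sample_rate_hz: float = 50.0,
) -> tuple[np.ndarray, ChewEventTrack]:
    """Generate one activity block as an (n_samples, 8) channel array (mm).

    Channel order follows :data:`ocochew.data_model.CHANNEL_ORDER`. Eating
    blocks also return the ground-truth chew-event times (s, block-relative).
    """
    if duration_s <= 0:
        raise ConfigError("duration_s must be positive")
    fs = sample_rate_hz
    n = int(round(duration_s * fs))
    block = np.zeros((n, 8))
    events = np.empty(0)

    if model.periodic and model.cheek_amp_mm > 0:
        base, events = _chew_magnitude(model, duration_s, fs, rng)
        mags = {}
        for region, target in (("C", model.cheek_amp_mm), ("T", model.temple_amp_mm)):
            share_r = rng.uniform(0.42, 0.58)  # chewing-side preference
            for side, share in (("R", share_r), ("L", 1.0 - share_r)):
                mags[f"O_{side}{region}"] = base * share
        total = mags["O_RC"] + mags["O_LC"]
        scale_c = model.cheek_amp_mm / max(total.mean(), 1e-12)
        total_t = mags["O_RT"] + mags["O_LT"]
        scale_t = model.temple_amp_mm / max(total_t.mean(), 1e-12)
        for key, scale in (("O_RC", scale_c), ("O_LC", scale_c), ("O_RT", scale_t), ("O_LT", scale_t)):
            mags[key] = mags[key] * scale
    elif model.cheek_amp_mm > 0 or model.temple_amp_mm > 0:
        mags = {}
        for region, target in (("C", model.cheek_amp_mm), ("T", model.temple_amp_mm)):
            m_r = _bandlimited_magnitude(model.bandwidth_hz, n, fs, rng)
            m_l = _bandlimited_magnitude(model.bandwidth_hz, n, fs, rng)
            scale = target / max((m_r + m_l).mean(), 1e-12)
            mags[f"O_R{region}"] = m_r * scale
            mags[f"O_L{region}"] = m_l * scale
    else:
        mags = {s: np.zeros(n) for s in ("O_RC", "O_LC", "O_RT", "O_LT")}

    for i, ch in enumerate(CHANNEL_ORDER):
        if ch.axis.value == "x":
            x, y = _project_xy(mags[ch.sensor.value], rng)
            block[:, i] = x
            block[:, i + 1] = y
    if model.noise_sd_mm > 0:
        block += rng.normal(0.0, model.noise_sd_mm, size=block.shape)
    return block, ChewEventTrack(event_times_s=events)


def simulate_cohort(spec: CohortSpec) -> list[CohortItem]:
    """Generate a deterministic cohort of recordings + annotations + chew events.

    Each participant gets an independent RNG substream seeded by
    ``(spec.seed, participant_index)`` and a log-normal amplitude multiplier
    shared across activities (so the per-participant activity ordering
    matches the population ordering), plus a smaller per-activity jitter.
    """
    items: list[CohortItem] = []
    fs = spec.sample_rate_hz
    for p in range(spec.n_participants):
        rng = np.random.default_rng([spec.seed, p])
        p_mult = float(np.exp(rng.normal(0.0, spec.per_participant_amp_multiplier_sd)))
        blocks: list[np.ndarray] = []
        intervals: list[tuple[str, float, float]] = []
        events: list[np.ndarray] = []
        cursor = 0.0
        for label, dur in spec.schedule:
            model = spec.model_for(label)
            jitter = float(np.exp(rng.normal(0.0, spec.per_activity_jitter_sd)))
            scaled = replace(
                model,
                cheek_amp_mm=model.cheek_amp_mm * p_mult * jitter,
                temple_amp_mm=model.temple_amp_mm * p_mult * jitter,
            )
            block, ev = simulate_activity(scaled, dur, rng, sample_rate_hz=fs)
            blocks.append(block)
            if label != "none":
                intervals.append((label, cursor, cursor + dur))
            if len(ev):
                events.append(ev.event_times_s + cursor)
            cursor += dur
        rec = OcoRecording(
            participant_id=f"P{p + 1:02d}",
            sample_rate_hz=fs,
            data=np.vstack(blocks),
        )
        track = AnnotationTrack(intervals=intervals)
        chew = ChewEventTrack(
            event_times_s=np.concatenate(events) if events else np.empty(0)
        )
        items.append(CohortItem(recording=rec, annotations=track, chew_events=chew))
    return items


def simulate_chew_segment(
    rate_hz: float,
    duration_s: float,
    snr_db: float,
    rng: np.random.Generator,
    sample_rate_hz: float = 50.0,
) -> tuple[np.ndarray, ChewEventTrack]:
    """Continuous chew train at a fixed rate with noise set by SNR.

    The per-axis noise standard deviation is chosen so that the noise power in
    the dominant (right-cheek) magnitude signal is ``snr_db`` decibels below
    the clean signal power. Used for controlled chew-counting experiments.
    """
    model = replace(
        DEFAULT_ACTIVITY_MODELS["eating"],
        rate_range_hz=(rate_hz, rate_hz),
        pause_range_s=(0.0, 0.0),
        bite_len_chews=(1000000, 1000000),
        noise_sd_mm=0.0,
    )
    block, events = simulate_activity(model, duration_s, rng, sample_rate_hz)
    rc_mag = np.hypot(block[:, 0], block[:, 1])
    p_sig = float(np.mean(rc_mag**2))
    # noise magnitude power on one sensor is 2*sigma^2 (two axes)
    sigma = np.sqrt(p_sig / (2.0 * 10.0 ** (snr_db / 10.0)))
    block = block + rng.normal(0.0, sigma, size=block.shape)
    return block, events
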