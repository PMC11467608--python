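"""Window-classification architectures and the training recipe.

Four classifiers map a fixed-length multichannel window to chewing /
nonchewing logits:

* ``cnn2d`` — 3 conv blocks (conv + group norm + max pool) over the
  (time x channel) plane, then two 128-unit fully connected layers.
* ``convlstm`` — the same conv stack feeding 2 LSTM layers (128 hidden
  units each); the final hidden state is classified.
* ``attention`` — 4 conv blocks with 64 feature maps, 2 LSTM layers and an
  additive-attention pooling layer over the LSTM output sequence.
* ``cnn1d`` — a single 256-filter 1-D convolution + max pool, flattened and
  fused with per-channel statistical features (mean, variance, absolute
  sum), through a 1024-unit fully connected layer.

The first three consume the time-domain tensor with the window's FFT
magnitudes (interpolated to window length, scaled by 1/window_len) stacked
as extra channels; ``cnn1d`` consumes time-domain plus statistical features
only.

Training: Adam (lr 1e-3), cross-entropy, batch size 256, up to 100 epochs,
orthogonal weight initialization, early stopping on validation F1-macro with
patience 15, best-validation weights restored.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from . import nn
from .errors import ConfigError, DataError
from .preprocess import WindowSet

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "WindowPredictions",
    "build_model",
    "train_model",
    "predict_windows",
]

Arch = Literal["cnn1d", "cnn2d", "convlstm", "attention"]


@dataclass(frozen=True)
class ModelConfig:
    arch: Arch
    window_len_samples: int
    n_channels: int
    n_freq_bins: int
    conv_kernel: tuple[int, int] = (5, 3)
    conv_channels: tuple[int, ...] = (16, 32, 64)
    #: per-block time-axis pooling; 4 in the first block keeps cost low at 50 Hz
    conv_time_pool: tuple[int, ...] = (4, 2, 2)
    attn_conv_channels: int = 64
    groupnorm_groups: int = 8
    lstm_hidden: int = 128
    attn_dim: int = 64
    cnn1d_filters: int = 256
    cnn1d_pool: int = 4
    cnn1d_fc: int = 1024
    fc_units: int = 128
    n_classes: int = 2
    dtype: str = "float32"  # float64 available for numerical verification

    def __post_init__(self) -> None:
        if self.arch not in ("cnn1d", "cnn2d", "convlstm", "attention"):
            raise ConfigError(f"unknown architecture {self.arch!r}")
        if self.window_len_samples < 8 or self.n_channels < 1:
            raise ConfigError("invalid input shape")

    @classmethod
    def for_window_set(cls, ws: WindowSet, arch: Arch, **overrides) -> "ModelConfig":
        return cls(
            arch=arch,
            window_len_samples=ws.window_len_samples,
            n_channels=ws.n_channels,
            n_freq_bins=ws.freq.shape[1],
            **overrides,
        )


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 256
    lr: float = 1e-3
    patience: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.patience < self.epochs:
            raise ConfigError("patience must be smaller than epochs")


@dataclass
class WindowPredictions:
    """Per-window chewing probability and hard label, time-aligned."""

    prob_chewing: np.ndarray
    label: np.ndarray
    window_start_s: np.ndarray
    window_s: float
    slide_s: float
    threshold: float = 0.5
    participant_ids: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.participant_ids is None:
            self.participant_ids = np.full(len(self.prob_chewing), "", dtype=object)

    def __len__(self) -> int:
        return len(self.prob_chewing)


class _Scaler:
    """Per-channel standardization fitted on training-fold windows."""

    def fit(self, ws: WindowSet) -> "_Scaler":
        self.time_mean = ws.windows.mean(axis=(0, 1))
        self.time_sd = np.maximum(ws.windows.std(axis=(0, 1)), 1e-9)
        self.freq_mean = ws.freq.mean(axis=(0, 1))
        self.freq_sd = np.maximum(ws.freq.std(axis=(0, 1)), 1e-9)
        stats = _stat_features(ws.windows)
        self.stat_mean = stats.mean(axis=0)
        self.stat_sd = np.maximum(stats.std(axis=0), 1e-9)
        return self

    def time(self, windows: np.ndarray) -> np.ndarray:
        return (windows - self.time_mean) / self.time_sd

    def freq(self, spectra: np.ndarray) -> np.ndarray:
        return (spectra - self.freq_mean) / self.freq_sd

    def stats(self, windows: np.ndarray) -> np.ndarray:
        return (_stat_features(windows) - self.stat_mean) / self.stat_sd


def _stat_features(windows: np.ndarray) -> np.ndarray:
    """Mean, variance, absolute sum per channel of the filtered windows."""
    return np.concatenate(
        [windows.mean(axis=1), windows.var(axis=1), np.abs(windows).sum(axis=1)],
        axis=1,
    )


def _interp_freq_to_time(freq: np.ndarray, L: int) -> np.ndarray:
    """Resample the (n, n_bins, C) spectrum to length L along the bin axis."""
    n_bins = freq.shape[1]
    xi = np.linspace(0.0, n_bins - 1.0, L)
    x0 = np.arange(n_bins)
    idx = np.clip(np.searchsorted(x0, xi) - 1, 0, n_bins - 2)
    w = (xi - idx) / 1.0
    return freq[:, idx, :] * (1.0 - w[None, :, None]) + freq[:, idx + 1, :] * w[None, :, None]


def _conv_block(
    c_in: int, c_out: int, kernel: tuple[int, int], groups: int, pool: tuple[int, int], rng
) -> list[nn.Layer]:
    g = groups if c_out % groups == 0 else 1
    return [
        nn.Conv2d(c_in, c_out, kernel, rng),
        nn.GroupNorm(g, c_out),
        nn.ReLU(),
        nn.MaxPool2d(*pool),
    ]


class _BaseNet:
    """Shared plumbing: input preparation, parameter bookkeeping."""

    uses_freq = True

    def __init__(self, cfg: ModelConfig, seed: int):
        self.cfg = cfg
        self.seed = seed
        self.dtype = np.dtype(cfg.dtype)
        self.scaler: _Scaler | None = None
        self._build(np.random.default_rng(seed))
        for p in self._params:
            p.astype(self.dtype)

    # -- architecture-specific -------------------------------------------
    def _build(self, rng: np.random.Generator) -> None:  # pragma: no cover
        raise NotImplementedError

    def _forward_net(self, inputs: dict, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def _backward_net(self, grad: np.ndarray) -> None:  # pragma: no cover
        raise NotImplementedError

    # -- shared -----------------------------------------------------------
    def params(self) -> list[nn.Param]:
        return self._params

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self._params))

    def prepare_inputs(self, ws: WindowSet) -> dict:
        if self.scaler is None:
            raise DataError("model has no fitted scaler; train it first")
        if ws.window_len_samples != self.cfg.window_len_samples or (
            ws.n_channels != self.cfg.n_channels
        ):
            raise ConfigError(
                "window set shape does not match the model's configured input"
            )
        t = self.scaler.time(ws.windows)  # (n, L, C)
        out = {"time": t}
        if self.uses_freq:
            f = _interp_freq_to_time(self.scaler.freq(ws.freq), t.shape[1])
            img = np.concatenate([t, f], axis=2)  # (n, L, 2C)
            out["image"] = img[:, None, :, :]  # (n, 1, L, 2C)
            del out["time"]
        else:
            out["stats"] = self.scaler.stats(ws.windows)
        return {k: np.ascontiguousarray(v, dtype=self.dtype) for k, v in out.items()}

    def forward(self, inputs: dict, train: bool = True) -> np.ndarray:
        return self._forward_net(inputs, train)

    def backward(self, grad: np.ndarray) -> None:
        self._backward_net(grad)

    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self._params]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self._params, state):
            p.value[...] = v


class _Cnn2d(_BaseNet):
    def _build(self, rng: np.random.Generator) -> None:
        cfg = self.cfg
        layers: list[nn.Layer] = []
        c_in, H, Wd = 1, cfg.window_len_samples, 2 * cfg.n_channels
        for idx, c_out in enumerate(cfg.conv_channels):
            tp = cfg.conv_time_pool[idx] if idx < len(cfg.conv_time_pool) else 2
            pool = (tp if H >= tp else 1, 2 if Wd >= 2 else 1)
            layers += _conv_block(c_in, c_out, cfg.conv_kernel, cfg.groupnorm_groups, pool, rng)
            c_in, H, Wd = c_out, H // pool[0], Wd // pool[1]
        layers.append(nn.Flatten())
        d = c_in * H * Wd
        layers += [
            nn.Dense(d, cfg.fc_units, rng),
            nn.ReLU(),
            nn.Dense(cfg.fc_units, cfg.fc_units, rng),
            nn.ReLU(),
            nn.Dense(cfg.fc_units, cfg.n_classes, rng),
        ]
        self.net = nn.Sequential(*layers)
        self._params = self.net.params()

    def _forward_net(self, inputs: dict, train: bool) -> np.ndarray:
        return self.net.forward(inputs["image"], train=train)

    def _backward_net(self, grad: np.ndarray) -> None:
        self.net.backward(grad)


class _SeqConvRecurrent(_BaseNet):
    """Conv stack -> sequence over the pooled time axis -> 2 LSTM layers."""

    attention = False

    def _build(self, rng: np.random.Generator) -> None:
        cfg = self.cfg
        layers: list[nn.Layer] = []
        if self.attention:
            channels = (cfg.attn_conv_channels,) * 4
        else:
            channels = cfg.conv_channels
        c_in, H, Wd = 1, cfg.window_len_samples, 2 * cfg.n_channels
        for idx, c_out in enumerate(channels):
            tp = cfg.conv_time_pool[idx] if idx < len(cfg.conv_time_pool) else 2
            pool = (tp if H >= tp else 1, 2 if Wd >= 2 else 1)
            layers += _conv_block(c_in, c_out, cfg.conv_kernel, cfg.groupnorm_groups, pool, rng)
            c_in, H, Wd = c_out, H // pool[0], Wd // pool[1]
        self.conv = nn.Sequential(*layers)
        self._seq_shape = (c_in, H, Wd)
        d_feat = c_in * Wd
        self.lstm1 = nn.LSTM(d_feat, cfg.lstm_hidden, rng)
        self.lstm2 = nn.LSTM(cfg.lstm_hidden, cfg.lstm_hidden, rng)
        self.head = nn.Dense(cfg.lstm_hidden, cfg.n_classes, rng)
        parts: list[nn.Layer] = [self.conv, self.lstm1, self.lstm2, self.head]
        if self.attention:
            self.attn = nn.AdditiveAttention(cfg.lstm_hidden, cfg.attn_dim, rng)
            parts.append(self.attn)
        self._params = [p for part in parts for p in part.params()]

    def _forward_net(self, inputs: dict, train: bool) -> np.ndarray:
        z = self.conv.forward(inputs["image"], train=train)  # (N, C, T', W')
        N, C, T, Wd = z.shape
        seq = z.transpose(0, 2, 1, 3).reshape(N, T, C * Wd)
        hs = self.lstm2.forward(self.lstm1.forward(seq, train=train), train=train)
        if self.attention:
            pooled = self.attn.forward(hs, train=train)
        else:
            pooled = hs[:, -1, :]
        self._hs_shape = hs.shape
        return self.head.forward(pooled, train=train)

    def _backward_net(self, grad: np.ndarray) -> None:
        g_pooled = self.head.backward(grad)
        if self.attention:
            g_hs = self.attn.backward(g_pooled)
        else:
            g_hs = np.zeros(self._hs_shape, dtype=g_pooled.dtype)
            g_hs[:, -1, :] = g_pooled
        g_seq = self.lstm1.backward(self.lstm2.backward(g_hs))
        N, T, _ = g_seq.shape
        C, _, Wd = self._seq_shape
        g_z = g_seq.reshape(N, T, C, Wd).transpose(0, 2, 1, 3)
        self.conv.backward(g_z)


class _ConvLstm(_SeqConvRecurrent):
    attention = False


class _AttentionNet(_SeqConvRecurrent):
    attention = True


class _Cnn1d(_BaseNet):
    """1-D conv over time fused with statistical features."""

    uses_freq = False

    def _build(self, rng: np.random.Generator) -> None:
        cfg = self.cfg
        k = (cfg.conv_kernel[0], 1)
        self.conv = nn.Sequential(
            nn.Conv2d(cfg.n_channels, cfg.cnn1d_filters, k, rng),
            nn.ReLU(),
            nn.MaxPool2d(cfg.cnn1d_pool, 1),
            nn.Flatten(),
        )
        d_conv = cfg.cnn1d_filters * (cfg.window_len_samples // cfg.cnn1d_pool)
        d_stats = 3 * cfg.n_channels
        self.fc1 = nn.Dense(d_conv + d_stats, cfg.cnn1d_fc, rng)
        self.relu = nn.ReLU()
        self.head = nn.Dense(cfg.cnn1d_fc, cfg.n_classes, rng)
        self._params = (
            self.conv.params() + self.fc1.params() + self.head.params()
        )

    def _forward_net(self, inputs: dict, train: bool) -> np.ndarray:
        x = inputs["time"].transpose(0, 2, 1)[..., None]  # (N, C, T, 1)
        flat = self.conv.forward(x, train=train)
        self._d_conv = flat.shape[1]
        joint = np.concatenate([flat, inputs["stats"]], axis=1)
        return self.head.forward(self.relu.forward(self.fc1.forward(joint)))

    def _backward_net(self, grad: np.ndarray) -> None:
        g_joint = self.fc1.backward(self.relu.backward(self.head.backward(grad)))
        self.conv.backward(g_joint[:, : self._d_conv])


_ARCHS = {
    "cnn2d": _Cnn2d,
    "convlstm": _ConvLstm,
    "attention": _AttentionNet,
    "cnn1d": _Cnn1d,
}


def build_model(cfg: ModelConfig, seed: int = 0):
    """Instantiate an untrained classifier for ``cfg`` (deterministic in seed)."""
    return _ARCHS[cfg.arch](cfg, seed)


def _f1_macro(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    f1s = []
    for cls in (0, 1):
        tp = np.sum((y_pred == cls) & (y_true == cls))
        fp = np.sum((y_pred == cls) & (y_true != cls))
        fn = np.sum((y_pred != cls) & (y_true == cls))
        denom = 2 * tp + fp + fn
        f1s.append(2 * tp / denom if denom else 0.0)
    return float(np.mean(f1s))


def train_model(
    model: _BaseNet,
    train_ws: WindowSet,
    val_ws: WindowSet,
    cfg: TrainConfig = TrainConfig(),
) -> tuple[_BaseNet, pd.DataFrame]:
    """Train with Adam/cross-entropy, early-stopping on validation F1-macro.

    Returns the model with its best-validation weights restored and a
    per-epoch history (loss, val_f1_macro).
    """
    y_train = np.asarray(train_ws.labels)
    if len(np.unique(y_train)) < 2:
        raise DataError("training labels contain a single class")
    model.scaler = _Scaler().fit(train_ws)
    X = model.prepare_inputs(train_ws)
    Xv = model.prepare_inputs(val_ws)
    y_val = np.asarray(val_ws.labels)

    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.params(), lr=cfg.lr)
    n = len(y_train)
    best_f1, best_state, best_epoch = -1.0, None, -1
    history = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch = {k: v[idx] for k, v in X.items()}
            logits = model.forward(batch, train=True)
            loss, grad = nn.softmax_cross_entropy(logits, y_train[idx])
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            losses.append(loss)
        val_pred = _predict_labels(model, Xv, batch_size=cfg.batch_size)
        f1 = _f1_macro(y_val, val_pred)
        history.append({"epoch": epoch, "loss": float(np.mean(losses)), "val_f1_macro": f1})
        if f1 >= best_f1:
            # ties keep the most-trained weights; patience still counts from
            # the last strict improvement
            best_state = model.get_state()
            if f1 > best_f1:
                best_epoch = epoch
            best_f1 = f1
        if epoch - best_epoch >= cfg.patience:
            break
    model.set_state(best_state)
    return model, pd.DataFrame(history)


def _predict_labels(model: _BaseNet, inputs: dict, batch_size: int = 256) -> np.ndarray:
    return (_predict_probs(model, inputs, batch_size) >= 0.5).astype(int)


def _predict_probs(model: _BaseNet, inputs: dict, batch_size: int = 256) -> np.ndarray:
    n = len(next(iter(inputs.values())))
    probs = np.empty(n)
    for start in range(0, n, batch_size):
        batch = {k: v[start : start + batch_size] for k, v in inputs.items()}
        logits = model.forward(batch, train=False)
        probs[start : start + batch_size] = nn.softmax_probs(logits)[:, 1]
    return probs


def predict_windows(
    model: _BaseNet, ws: WindowSet, threshold: float = 0.5
) -> WindowPredictions:
    """Chewing probability (softmax) and thresholded label per window."""
    inputs = model.prepare_inputs(ws)
    probs = _predict_probs(model, inputs)
    return WindowPredictions(
        prob_chewing=probs,
        label=(probs >= threshold).astype(int),
        window_start_s=ws.window_start_s.copy(),
        window_s=ws.window_s,
        slide_s=ws.slide_s,
        threshold=threshold,
        participant_ids=ws.participant_ids.copy(),
    )
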