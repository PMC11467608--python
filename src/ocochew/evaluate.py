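"""Leave-one-group-out evaluation of the chewing-detection pipeline.

One fold per participant: the participant is the held-out test group, the
cyclically next participant is the validation group, and the rest are
training data — so every reported number is person-independent. Window
metrics (precision, recall, F1 with chewing as the positive class) are
computed on windows pooled across test folds; segment-level detection uses
the >50% positive-window criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import AnnotationTrack
from .errors import ConfigError, DataError
from .models import (
    ModelConfig,
    TrainConfig,
    WindowPredictions,
    build_model,
    predict_windows,
    train_model,
)
from .postprocess import (
    EatingSegment,
    analyze_segments,
    estimate_hmm_params,
    extract_segments,
    smooth_predictions,
)
from .preprocess import concat_window_sets, segment_windows
from .simulate import CohortItem

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "SegmentReport",
    "logo_splits",
    "window_metrics",
    "fp_rate_by_activity",
    "segment_detection",
    "logo_evaluate",
    "run_experiment_grid",
    "EvalResult",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n_windows(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    precision: float
    recall: float
    f1: float
    precision_neg: float
    recall_neg: float
    f1_neg: float
    f1_macro: float
    confusion: ConfusionMatrix
    degenerate: bool  # true if any metric had a zero denominator


@dataclass(frozen=True)
class SegmentReport:
    total_es: int
    detected_es: int
    false_es: int
    mean_false_duration_min: float


def logo_splits(
    participant_ids: Sequence[str],
) -> list[tuple[tuple[str, ...], str, str]]:
    """One (train_ids, val_id, test_id) split per participant.

    The validation participant is the cyclically next id after the test
    participant; train is everything else.
    """
    ids = list(participant_ids)
    if len(ids) < 3:
        raise ConfigError("leave-one-group-out needs at least 3 participants")
    if len(set(ids)) != len(ids):
        raise ConfigError("participant ids must be unique")
    splits = []
    for i, test in enumerate(ids):
        val = ids[(i + 1) % len(ids)]
        train = tuple(p for p in ids if p not in (test, val))
        splits.append((train, val, test))
    return splits


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    return (num / den, False) if den else (0.0, True)


def window_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> MetricsReport:
    """Precision/recall/F1 (chewing positive), per-class and macro."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise DataError("label arrays must have equal length")
    for arr in (y_true, y_pred):
        if np.any((arr != 0) & (arr != 1)):
            raise DataError("labels must be binary (0 = nonchewing, 1 = chewing)")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    prec, d1 = _safe_div(tp, tp + fp)
    rec, d2 = _safe_div(tp, tp + fn)
    f1, d3 = _safe_div(2 * prec * rec, prec + rec)
    prec_n, d4 = _safe_div(tn, tn + fn)
    rec_n, d5 = _safe_div(tn, tn + fp)
    f1_n, d6 = _safe_div(2 * prec_n * rec_n, prec_n + rec_n)
    return MetricsReport(
        precision=prec,
        recall=rec,
        f1=f1,
        precision_neg=prec_n,
        recall_neg=rec_n,
        f1_neg=f1_n,
        f1_macro=(f1 + f1_n) / 2.0,
        confusion=ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn),
        degenerate=any((d1, d2, d3, d4, d5, d6)),
    )


def _window_activity_labels(
    preds: WindowPredictions, track: AnnotationTrack
) -> np.ndarray:
    """Majority activity per window (by overlap duration)."""
    out = np.empty(len(preds), dtype=object)
    for i, t0 in enumerate(preds.window_start_s):
        t1 = t0 + preds.window_s
        best, best_ov = "none", 0.0
        for label, s, e in track.intervals:
            ov = min(t1, e) - max(t0, s)
            if ov > best_ov:
                best, best_ov = label, ov
        if best_ov < (t1 - t0) / 2.0:
            best = "none" if best_ov == 0.0 else best
        out[i] = best
    return out


def fp_rate_by_activity(
    preds: WindowPredictions, track: AnnotationTrack
) -> pd.DataFrame:
    """Fraction of each noneating activity's windows predicted as chewing."""
    activities = _window_activity_labels(preds, track)
    noneat = activities != "eating"
    rows = []
    for activity in sorted(set(activities[noneat])):
        mask = activities == activity
        rows.append(
            {
                "activity": activity,
                "n_windows": int(mask.sum()),
                "fp_rate": float(preds.label[mask].mean()),
            }
        )
    rows.append(
        {
            "activity": "overall",
            "n_windows": int(noneat.sum()),
            "fp_rate": float(preds.label[noneat].mean()) if noneat.any() else 0.0,
        }
    )
    return pd.DataFrame(rows)


def segment_detection(
    true_segments: Sequence[tuple[float, float]],
    preds: WindowPredictions,
    states: np.ndarray | None = None,
    strict: bool = True,
) -> SegmentReport:
    """Segment-level detection bookkeeping.

    A true segment counts as detected when the fraction of its windows
    (windows whose centre lies inside the segment) predicted as chewing
    exceeds 50% (``strict``; ``>=`` when ``strict=False``). Predicted
    segments — maximal runs of the smoothed states if given, else of the raw
    labels — that overlap no true segment count as false detections.
    """
    pos = np.asarray(states).astype(int) if states is not None else preds.label
    centers = preds.window_start_s + preds.window_s / 2.0
    detected = 0
    for s, e in true_segments:
        inside = (centers >= s) & (centers < e)
        if not inside.any():
            continue
        frac = preds.label[inside].mean() if states is None else pos[inside].mean()
        if (frac > 0.5) if strict else (frac >= 0.5):
            detected += 1
    pred_segments = extract_segments(pos, preds.window_start_s, preds.window_s)
    false_durations = []
    for seg in pred_segments:
        if not any(min(seg.end_s, e) > max(seg.start_s, s) for s, e in true_segments):
            false_durations.append(seg.duration_s)
    return SegmentReport(
        total_es=len(true_segments),
        detected_es=detected,
        false_es=len(false_durations),
        mean_false_duration_min=float(np.mean(false_durations) / 60.0)
        if false_durations
        else 0.0,
    )


@dataclass
class EvalResult:
    metrics: MetricsReport
    segment_report: SegmentReport
    fp_rates: pd.DataFrame
    per_fold: pd.DataFrame
    test_hours: float
    y_true: np.ndarray
    y_pred: np.ndarray
    segments: list[EatingSegment] = field(default_factory=list)


def logo_evaluate(
    dataset: Sequence[CohortItem],
    arch: str = "convlstm",
    sensors: str = "temple+cheek",
    window_s: float = 4.0,
    slide_s: float = 1.0,
    train_cfg: TrainConfig = TrainConfig(),
    use_hmm: bool = True,
    analyze_chews: bool = False,
    model_overrides: dict | None = None,
) -> EvalResult:
    """Full leave-one-participant-out evaluation of one configuration."""
    by_id = {item.recording.participant_id: item for item in dataset}
    window_sets = {
        pid: segment_windows(
            item.recording, item.annotations, window_s=window_s, slide_s=slide_s, sensors=sensors
        )
        for pid, item in by_id.items()
    }
    splits = logo_splits(list(by_id))
    all_true, all_pred = [], []
    fold_rows = []
    fp_frames = []
    seg_totals = {"total_es": 0, "detected_es": 0, "false_es": 0}
    false_durs: list[float] = []
    segments_out: list[EatingSegment] = []
    test_hours = 0.0
    for fold, (train_ids, val_id, test_id) in enumerate(splits):
        train_ws = concat_window_sets([window_sets[p] for p in train_ids])
        val_ws = window_sets[val_id]
        test_ws = window_sets[test_id]
        fold_seed = train_cfg.seed * 1000 + fold
        cfg = ModelConfig.for_window_set(train_ws, arch, **(model_overrides or {}))
        model = build_model(cfg, seed=fold_seed)
        model, history = train_model(
            model,
            train_ws,
            val_ws,
            TrainConfig(
                epochs=train_cfg.epochs,
                batch_size=train_cfg.batch_size,
                lr=train_cfg.lr,
                patience=train_cfg.patience,
                seed=fold_seed,
            ),
        )
        preds = predict_windows(model, test_ws)
        states = None
        if use_hmm:
            train_preds = predict_windows(model, train_ws)
            hmm = estimate_hmm_params(train_ws.labels, train_preds.label)
            states = smooth_predictions(preds, hmm)
        item = by_id[test_id]
        report = segment_detection(item.annotations.eating_segments(), preds, states=states)
        seg_totals["total_es"] += report.total_es
        seg_totals["detected_es"] += report.detected_es
        seg_totals["false_es"] += report.false_es
        if report.false_es:
            false_durs += [report.mean_false_duration_min] * report.false_es
        if analyze_chews and states is not None:
            segs = extract_segments(states, preds.window_start_s, preds.window_s)
            segments_out += analyze_segments(item.recording, segs)
        fp_frames.append(fp_rate_by_activity(preds, item.annotations).assign(fold=fold))
        fold_metrics = window_metrics(test_ws.labels, preds.label)
        fold_rows.append(
            {
                "fold": fold,
                "test_id": test_id,
                "val_id": val_id,
                "n_epochs": len(history),
                "f1": fold_metrics.f1,
                "precision": fold_metrics.precision,
                "recall": fold_metrics.recall,
            }
        )
        all_true.append(test_ws.labels)
        all_pred.append(preds.label)
        test_hours += item.recording.duration_s / 3600.0

    y_true = np.concatenate(all_true)
    y_pred = np.concatenate(all_pred)
    fp_all = (
        pd.concat(fp_frames, ignore_index=True)
        .groupby("activity", as_index=False)
        .apply(
            lambda g: pd.Series(
                {
                    "n_windows": g.n_windows.sum(),
                    "fp_rate": np.average(g.fp_rate, weights=np.maximum(g.n_windows, 1)),
                }
            ),
            include_groups=False,
        )
        .reset_index(drop=True)
    )
    return EvalResult(
        metrics=window_metrics(y_true, y_pred),
        segment_report=SegmentReport(
            total_es=seg_totals["total_es"],
            detected_es=seg_totals["detected_es"],
            false_es=seg_totals["false_es"],
            mean_false_duration_min=float(np.mean(false_durs)) if false_durs else 0.0,
        ),
        fp_rates=fp_all,
        per_fold=pd.DataFrame(fold_rows),
        test_hours=test_hours,
        y_true=y_true,
        y_pred=y_pred,
        segments=segments_out,
    )


def run_experiment_grid(
    dataset: Sequence[CohortItem],
    archs: Sequence[str] = ("convlstm",),
    sensor_subsets: Sequence[str] = ("temple+cheek",),
    window_sizes: Sequence[float] = (4.0,),
    slide_s: float = 1.0,
    train_cfg: TrainConfig = TrainConfig(),
    use_hmm: bool = True,
    model_overrides: dict | None = None,
) -> pd.DataFrame:
    """LOGO-evaluate every (arch, sensor subset, window size) grid cell."""
    rows = []
    for arch in archs:
        for sensors in sensor_subsets:
            for window_s in window_sizes:
                res = logo_evaluate(
                    dataset,
                    arch=arch,
                    sensors=sensors,
                    window_s=window_s,
                    slide_s=slide_s,
                    train_cfg=train_cfg,
                    use_hmm=use_hmm,
                    model_overrides=model_overrides,
                )
                rows.append(
                    {
                        "arch": arch,
                        "sensors": sensors,
                        "window_s": window_s,
                        "precision": res.metrics.precision,
                        "recall": res.metrics.recall,
                        "f1": res.metrics.f1,
                        "f1_macro": res.metrics.f1_macro,
                        "detected_es": res.segment_report.detected_es,
                        "total_es": res.segment_report.total_es,
                        "false_es": res.segment_report.false_es,
                    }
                )
    return pd.DataFrame(rows)
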