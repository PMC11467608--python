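import numpy as np
import pandas as pd
import pytest

from ocochew.data_model import AnnotationTrack
from ocochew.errors import ConfigError, DataError
from ocochew.evaluate import (
    fp_rate_by_activity,
    logo_splits,
    run_experiment_grid,
    segment_detection,
    window_metrics,
)
from ocochew.models import TrainConfig, WindowPredictions
from ocochew.simulate import CohortSpec, default_detection_schedule, simulate_cohort


class TestLogoSplits:
    def test_cyclic_rule(self):
        splits = logo_splits(["A", "B", "C"])
        assert len(splits) == 3
        by_test = {t: (tr, v) for tr, v, t in splits}
        assert by_test["A"] == (("C",), "B")

    def test_each_id_tested_once_and_roles_disjoint(self):
        ids = [f"P{i}" for i in range(5)]
        splits = logo_splits(ids)
        assert sorted(t for _, _, t in splits) == sorted(ids)
        for train, val, test in splits:
            assert val != test
            assert val not in train and test not in train
            assert len(train) == 3

    def test_too_few_rejected(self):
        with pytest.raises(ConfigError):
            logo_splits(["A", "B"])


class TestWindowMetrics:
    def test_direct_formula(self):
        y_true = np.array([1] * 10 + [0])
        y_pred = np.array([1] * 9 + [0] + [1])
        m = window_metrics(y_true, y_pred)
        assert m.precision == pytest.approx(0.9)
        assert m.recall == pytest.approx(0.9)
        assert m.f1 == pytest.approx(0.9)
        assert m.confusion.n_windows == 11

    def test_perfect_prediction(self):
        y = np.array([0, 1, 1, 0])
        m = window_metrics(y, y)
        assert (m.precision, m.recall, m.f1, m.f1_macro) == (1.0, 1.0, 1.0, 1.0)
        assert not m.degenerate

    def test_zero_denominator_flagged(self):
        m = window_metrics(np.zeros(5, dtype=int), np.zeros(5, dtype=int))
        assert m.f1 == 0.0 and m.degenerate

    def test_matches_counting_oracle_and_sklearn(self, rng):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        y_true = rng.integers(0, 2, size=200)
        y_pred = rng.integers(0, 2, size=200)
        m = window_metrics(y_true, y_pred)
        # independent tally
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 1)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 0)
        assert m.precision == pytest.approx(tp / (tp + fp))
        assert m.recall == pytest.approx(tp / (tp + fn))
        p, r, f, _ = sklearn_metrics.precision_recall_fscore_support(
            y_true, y_pred, average="binary", pos_label=1
        )
        assert (m.precision, m.recall, m.f1) == pytest.approx((p, r, f))
        assert m.f1_macro == pytest.approx(
            sklearn_metrics.f1_score(y_true, y_pred, average="macro")
        )

    def test_invalid_labels_rejected(self):
        with pytest.raises(DataError):
            window_metrics(np.array([0, 2]), np.array([0, 1]))


def _preds(labels, window_s=4.0, slide_s=1.0):
    labels = np.asarray(labels, dtype=int)
    return WindowPredictions(
        prob_chewing=labels.astype(float),
        label=labels,
        window_start_s=np.arange(len(labels)) * slide_s,
        window_s=window_s,
        slide_s=slide_s,
    )


class TestFpRateByActivity:
    def test_no_false_positives(self):
        track = AnnotationTrack(intervals=[("speaking", 0.0, 50.0)])
        table = fp_rate_by_activity(_preds(np.zeros(40)), track)
        assert np.all(table.fp_rate == 0.0)

    def test_one_fp_among_speaking(self):
        track = AnnotationTrack(intervals=[("speaking", 0.0, 104.0)])
        labels = np.zeros(100)
        labels[7] = 1
        table = fp_rate_by_activity(_preds(labels), track)
        speaking = table[table.activity == "speaking"].iloc[0]
        assert speaking.fp_rate == pytest.approx(0.01)
        overall = table[table.activity == "overall"].iloc[0]
        assert overall.fp_rate == pytest.approx(1 / 100)  # FP / (FP + TN)


class TestSegmentDetection:
    def test_six_of_ten_detected(self):
        labels = np.array([1] * 6 + [0] * 4)
        # one true segment covering all 10 window centres
        report = segment_detection([(0.0, 14.0)], _preds(labels))
        assert report.detected_es == 1

    def test_five_of_ten_not_detected_strict(self):
        labels = np.array([1] * 5 + [0] * 5)
        report = segment_detection([(0.0, 14.0)], _preds(labels))
        assert report.detected_es == 0
        report_loose = segment_detection([(0.0, 14.0)], _preds(labels), strict=False)
        assert report_loose.detected_es == 1

    def test_zero_predicted_segments_no_false(self):
        report = segment_detection([(0.0, 14.0)], _preds(np.zeros(10)))
        assert report.false_es == 0 and report.detected_es == 0

    def test_false_segment_outside_truth(self):
        labels = np.zeros(60)
        labels[40:46] = 1  # run far outside the true segment
        report = segment_detection([(0.0, 10.0)], _preds(labels))
        assert report.false_es == 1
        assert report.mean_false_duration_min == pytest.approx(9.0 / 60.0)

    def test_smoothed_states_take_precedence(self):
        labels = np.array([1] * 6 + [0] * 4)
        states = np.zeros(10, dtype=int)
        report = segment_detection([(0.0, 14.0)], _preds(labels), states=states)
        assert report.detected_es == 0 and report.false_es == 0


SMALL_MODEL = dict(
    conv_channels=(4, 4),
    conv_time_pool=(4, 2),
    groupnorm_groups=2,
    lstm_hidden=8,
    attn_dim=4,
    attn_conv_channels=4,
    cnn1d_filters=8,
    cnn1d_fc=16,
    fc_units=8,
)


@pytest.fixture(scope="module")
def tiny_cohort():
    spec = CohortSpec(n_participants=3, schedule=default_detection_schedule(90.0), seed=21)
    return simulate_cohort(spec)


class TestExperimentGrid:
    def test_single_cell_and_channel_counts(self, tiny_cohort):
        from ocochew.preprocess import segment_windows

        cheek_ws = segment_windows(
            tiny_cohort[0].recording, tiny_cohort[0].annotations, sensors="cheek"
        )
        assert cheek_ws.n_channels == 4
        both_ws = segment_windows(
            tiny_cohort[0].recording, tiny_cohort[0].annotations, sensors="temple+cheek"
        )
        assert both_ws.n_channels == 8

        table = run_experiment_grid(
            tiny_cohort,
            archs=("cnn1d",),
            sensor_subsets=("cheek",),
            window_sizes=(4.0,),
            slide_s=2.0,
            train_cfg=TrainConfig(epochs=3, patience=1, batch_size=16, seed=2),
            use_hmm=False,
            model_overrides=SMALL_MODEL,
        )
        assert len(table) == 1
        assert set(["arch", "sensors", "window_s", "f1"]).issubset(table.columns)

    def test_grid_deterministic(self, tiny_cohort):
        kwargs = dict(
            archs=("cnn1d",),
            sensor_subsets=("right",),
            window_sizes=(4.0,),
            slide_s=2.0,
            train_cfg=TrainConfig(epochs=2, patience=1, batch_size=16, seed=3),
            use_hmm=True,
            model_overrides=SMALL_MODEL,
        )
        a = run_experiment_grid(tiny_cohort, **kwargs)
        b = run_experiment_grid(tiny_cohort, **kwargs)
        pd.testing.assert_frame_equal(a, b)
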