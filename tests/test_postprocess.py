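import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ocochew.data_model import OcoRecording
from ocochew.errors import ConfigError, DataError
from ocochew.postprocess import (
    EatingSegment,
    HmmParams,
    count_chews,
    estimate_chewing_rate,
    estimate_hmm_params,
    extract_segments,
    select_max_rms_channel,
    smooth_predictions,
)
from ocochew.simulate import simulate_chew_segment


def viterbi_oracle(obs, params):
    """Brute force: maximize the joint probability over all 2^n state paths."""
    best_path, best_lp = None, -np.inf
    init = np.asarray(params.initial)
    trans = np.asarray(params.transition)
    e_pos = np.asarray(params.emission_pos)
    for path in itertools.product([0, 1], repeat=len(obs)):
        lp = np.log(init[path[0]])
        lp += np.log(e_pos[path[0]] if obs[0] else 1 - e_pos[path[0]])
        for t in range(1, len(obs)):
            lp += np.log(trans[path[t - 1], path[t]])
            lp += np.log(e_pos[path[t]] if obs[t] else 1 - e_pos[path[t]])
        if lp > best_lp:
            best_lp, best_path = lp, path
    return np.array(best_path)


class TestViterbi:
    def test_all_zero_observations(self):
        states = smooth_predictions(np.zeros(30, dtype=int), HmmParams())
        np.testing.assert_array_equal(states, 0)

    def test_isolated_spike_suppressed(self):
        obs = np.zeros(51, dtype=int)
        obs[25] = 1
        params = HmmParams(
            initial=(0.95, 0.05),
            transition=((0.95, 0.05), (0.05, 0.95)),
            emission_pos=(0.05, 0.9),
        )
        np.testing.assert_array_equal(smooth_predictions(obs, params), 0)

    def test_short_gaps_bridged(self):
        obs = np.zeros(50, dtype=int)
        obs[10:40] = 1
        obs[20] = 0
        obs[30] = 0
        params = HmmParams(
            initial=(0.95, 0.05),
            transition=((0.95, 0.05), (0.05, 0.95)),
            emission_pos=(0.05, 0.9),
        )
        states = smooth_predictions(obs, params)
        runs = np.flatnonzero(np.diff(np.r_[0, states, 0]) != 0)
        assert len(runs) == 2  # one contiguous eating run
        assert states[20] == 1 and states[30] == 1

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 13))
        obs = rng.integers(0, 2, size=n)
        p_stay0, p_stay1 = rng.uniform(0.6, 0.99, size=2)
        params = HmmParams(
            initial=tuple(rng.dirichlet([1, 1])),
            transition=((p_stay0, 1 - p_stay0), (1 - p_stay1, p_stay1)),
            emission_pos=(rng.uniform(0.01, 0.4), rng.uniform(0.6, 0.99)),
        )
        np.testing.assert_array_equal(
            smooth_predictions(obs, params), viterbi_oracle(obs, params)
        )

    def test_matches_hmmlearn(self):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(3)
        obs = rng.integers(0, 2, size=200)
        params = HmmParams()
        model = hmmlearn.CategoricalHMM(n_components=2, init_params="")
        model.startprob_ = np.asarray(params.initial)
        model.transmat_ = np.asarray(params.transition)
        e = np.asarray(params.emission_pos)
        model.emissionprob_ = np.stack([1 - e, e], axis=1)
        _, ref = model.decode(obs.reshape(-1, 1), algorithm="viterbi")
        np.testing.assert_array_equal(smooth_predictions(obs, params), ref)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_smoothing_never_splits_runs(self, seed):
        # persistence-dominant chains only merge or delete prediction runs
        rng = np.random.default_rng(seed)
        obs = rng.integers(0, 2, size=60)
        params = HmmParams(
            transition=((0.95, 0.05), (0.08, 0.92)),
            emission_pos=(0.1, 0.85),
        )
        states = smooth_predictions(obs, params)
        n_runs = lambda x: len(np.flatnonzero(np.diff(np.r_[0, x, 0]) == 1))
        assert n_runs(states) <= n_runs(obs)

    def test_degenerate_params_rejected(self):
        with pytest.raises(ConfigError):
            HmmParams(transition=((1.2, -0.2), (0.5, 0.5)))
        with pytest.raises(ConfigError):
            HmmParams(emission_pos=(0.0, 0.9))


class TestEstimateHmmParams:
    def test_persistence_from_run_lengths(self):
        y = np.array([0] * 20 + [1] * 10 + [0] * 20 + [1] * 10)
        params = estimate_hmm_params(y, y)
        assert params.transition[1][1] == pytest.approx(1 - 1 / 10)
        assert params.transition[0][0] == pytest.approx(1 - 1 / 20)

    def test_emissions_from_confusion(self):
        y_true = np.array([0] * 50 + [1] * 50)
        y_pred = y_true.copy()
        y_pred[:5] = 1  # 10% FP rate
        y_pred[50:60] = 0  # 80% recall
        params = estimate_hmm_params(y_true, y_pred, min_persistence=0.0)
        assert params.emission_pos[0] == pytest.approx(0.1)
        assert params.emission_pos[1] == pytest.approx(0.8)


class TestExtractSegments:
    def test_single_run(self):
        segs = extract_segments([0, 1, 1, 0], np.arange(4.0), window_s=4.0)
        assert len(segs) == 1
        assert segs[0].start_s == 1.0 and segs[0].end_s == 6.0
        assert segs[0].n_windows == 2

    def test_all_zeros(self):
        assert extract_segments(np.zeros(10), np.arange(10.0), 4.0) == []

    def test_two_runs(self):
        segs = extract_segments([1, 1, 0, 1], np.arange(4.0), 4.0)
        assert len(segs) == 2
        assert segs[1].start_s == 3.0 and segs[1].end_s == 7.0


def _recording_with_amplitudes(cheek=1.0, temple=0.1, n=500):
    rng = np.random.default_rng(0)
    data = np.zeros((n, 8))
    data[:, 0:4] = cheek * rng.normal(size=(n, 4))
    data[:, 4:8] = temple * rng.normal(size=(n, 4))
    return OcoRecording(participant_id="A", sample_rate_hz=50.0, data=data)


class TestMaxRmsChannel:
    def test_cheek_dominates(self):
        rec = _recording_with_amplitudes(cheek=1.0, temple=0.1)
        name, _ = select_max_rms_channel(rec, EatingSegment(0.0, 10.0, n_windows=1))
        assert name in ("O_RC", "O_LC")

    def test_tie_breaks_to_canonical_order(self, zero_recording):
        name, _ = select_max_rms_channel(zero_recording, EatingSegment(0.0, 10.0, n_windows=1))
        assert name == "O_RC"

    def test_selected_rms_is_max(self):
        rec = _recording_with_amplitudes()
        seg = EatingSegment(0.0, 10.0, n_windows=1)
        _, sig = select_max_rms_channel(rec, seg)
        from ocochew.preprocess import vector_magnitude
        from ocochew.data_model import Axis, Sensor

        best = np.sqrt(np.mean(sig**2))
        for s in Sensor:
            mag = vector_magnitude(rec.channel(s, Axis.X)[:500], rec.channel(s, Axis.Y)[:500])
            assert best >= np.sqrt(np.mean(mag**2)) - 1e-12


def _chew_magnitude_signal(rate, duration, snr_db, seed):
    block, events = simulate_chew_segment(rate, duration, snr_db, np.random.default_rng(seed))
    from ocochew.preprocess import vector_magnitude

    return vector_magnitude(block[:, 0], block[:, 1]), events


class TestChewCounting:
    def test_clean_train_counted_exactly(self):
        sig, events = _chew_magnitude_signal(1.5, 20.0, snr_db=60.0, seed=1)
        count, times = count_chews(sig, 50.0)
        assert abs(count - 30) <= 1
        assert np.all(times >= 0) and np.all(times <= 20.0)

    def test_constant_signal_zero_chews(self):
        count, times = count_chews(np.full(500, 0.2), 50.0)
        assert count == 0 and len(times) == 0

    def test_noisy_train_within_five_percent(self):
        errors = []
        for seed in range(10):
            rate = np.random.default_rng(seed).uniform(0.8, 2.3)
            sig, events = _chew_magnitude_signal(rate, 30.0, snr_db=10.0, seed=seed)
            count, _ = count_chews(sig, 50.0)
            errors.append(abs(count - len(events)) / len(events))
        assert np.mean(np.asarray(errors) <= 0.05) >= 0.9

    def test_too_short_rejected(self):
        with pytest.raises(DataError):
            count_chews(np.zeros(50), 50.0)


class TestChewingRate:
    def test_pure_tone(self):
        t = np.arange(1000) / 50.0
        sig = 0.1 + 0.05 * np.sin(2 * np.pi * 1.5 * t)
        assert estimate_chewing_rate(sig, 50.0) == pytest.approx(1.5, abs=0.03)

    @pytest.mark.parametrize("rate", [0.8, 1.2, 2.3])
    def test_synthetic_rates_recovered(self, rate):
        sig, _ = _chew_magnitude_signal(rate, 25.0, snr_db=20.0, seed=int(rate * 10))
        assert estimate_chewing_rate(sig, 50.0) == pytest.approx(rate, abs=0.1)

    def test_rate_times_duration_matches_count(self):
        sig, events = _chew_magnitude_signal(1.6, 25.0, snr_db=30.0, seed=5)
        rate = estimate_chewing_rate(sig, 50.0)
        count, _ = count_chews(sig, 50.0)
        assert rate * 25.0 == pytest.approx(count, rel=0.15)

    def test_too_short_rejected(self):
        with pytest.raises(DataError):
            estimate_chewing_rate(np.zeros(100), 50.0)
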