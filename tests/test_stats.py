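import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as scipy_stats

from ocochew.data_model import AnnotationTrack, OcoRecording
from ocochew.errors import DataError
from ocochew.simulate import CohortItem
from ocochew.stats import (
    bonferroni_adjust,
    paired_activity_tests,
    participant_activity_means,
    significance_annotation,
    wilcoxon_signed_rank,
)


def wilcoxon_enumeration_oracle(d):
    """Exhaustive 2^n sign-flip null distribution of W+ (midranks, two-sided)."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = scipy_stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = np.array(
        [np.sum(ranks[np.array(signs, dtype=bool)]) for signs in itertools.product([0, 1], repeat=n)]
    )
    cdf = np.mean(ws <= w_obs + 1e-12)
    sf = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(cdf, sf))


class TestWilcoxon:
    def test_all_positive_differences_n6(self):
        b = np.arange(6, dtype=float)
        w, p = wilcoxon_signed_rank(b + 1.0, b)
        assert w == 0.0  # min(W+, W-) with every difference positive
        assert p == pytest.approx(2.0 / 64.0)

    def test_antisymmetric_differences_give_p_one(self):
        a = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
        w, p = wilcoxon_signed_rank(a, np.zeros(6))
        assert p == pytest.approx(1.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        # mix of continuous and tied integer-valued differences
        if rng.random() < 0.5:
            d = rng.normal(0.3, 1.0, size=n)
        else:
            d = rng.integers(-3, 4, size=n).astype(float)
        d = d[d != 0]
        if d.size < 5:
            d = np.concatenate([d, rng.normal(0.5, 1.0, size=5 - d.size)])
        _, p = wilcoxon_signed_rank(d, np.zeros_like(d))
        assert p == pytest.approx(wilcoxon_enumeration_oracle(d))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_scipy_exact_without_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 20))
        a = rng.normal(0.5, 1.0, size=n)
        b = rng.normal(0.0, 1.0, size=n)
        w, p = wilcoxon_signed_rank(a, b)
        ref = scipy_stats.wilcoxon(a, b, zero_method="wilcox", method="exact")
        assert w == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_large_n_close_to_scipy_normal_approx(self, rng):
        a = rng.normal(0.3, 1.0, size=60)
        b = rng.normal(0.0, 1.0, size=60)
        _, p = wilcoxon_signed_rank(a, b)
        ref = scipy_stats.wilcoxon(a, b, zero_method="wilcox", method="approx", correction=True)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_degenerate_inputs(self):
        with pytest.raises(DataError):
            wilcoxon_signed_rank(np.ones(6), np.ones(6))
        with pytest.raises(DataError):
            wilcoxon_signed_rank([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])


class TestBonferroni:
    def test_examples(self):
        adj, rej = bonferroni_adjust([0.01, 0.2, 0.5])
        np.testing.assert_allclose(adj, [0.03, 0.6, 1.0])
        assert list(rej) == [True, False, False]

    def test_single_p_unchanged(self):
        adj, _ = bonferroni_adjust([0.2])
        assert adj[0] == pytest.approx(0.2)

    def test_monotone(self, rng):
        p = np.sort(rng.uniform(size=10))
        adj, _ = bonferroni_adjust(p)
        assert np.all(np.diff(adj) >= 0)


@pytest.mark.parametrize(
    "p,expected",
    [(0.03, "*"), (0.5, "ns"), (1e-5, "****"), (0.005, "**"), (0.0005, "***"), (1e-4, "****")],
)
def test_significance_annotation(p, expected):
    assert significance_annotation(p) == expected


def _constant_item(pid, cheek_levels, fs=50.0):
    """Recording whose smoothed combined cheek magnitude is piecewise constant.

    ``cheek_levels``: list of (label, duration_s, combined_cheek_mm).
    """
    blocks, intervals, cursor = [], [], 0.0
    for label, dur, level in cheek_levels:
        n = int(dur * fs)
        block = np.zeros((n, 8))
        block[:, 0] = level / 2.0  # O_RC_x
        block[:, 2] = level / 2.0  # O_LC_x
        block[:, 4] = level / 4.0  # temple at half the cheek level
        block[:, 6] = level / 4.0
        blocks.append(block)
        intervals.append((label, cursor, cursor + dur))
        cursor += dur
    rec = OcoRecording(participant_id=pid, sample_rate_hz=fs, data=np.vstack(blocks))
    return CohortItem(rec, AnnotationTrack(intervals=intervals), chew_events=None)


class TestParticipantMeans:
    def test_constant_magnitude(self):
        item = _constant_item(
            "P1",
            [("eating", 4.0, 0.1), ("speaking", 4.0, 0.05), ("clenching", 4.0, 0.01)],
        )
        means = participant_activity_means([item])
        cheek_eat = means.query("region == 'cheek' and activity == 'eating'").mean_movement_mm
        assert cheek_eat.iloc[0] == pytest.approx(0.1, rel=1e-6)

    def test_pooled_mean_of_equal_intervals(self):
        item = _constant_item(
            "P1",
            [
                ("eating", 4.0, 0.1),
                ("speaking", 4.0, 0.05),
                ("eating", 4.0, 0.3),
                ("clenching", 4.0, 0.01),
            ],
        )
        means = participant_activity_means([item])
        cheek_eat = means.query("region == 'cheek' and activity == 'eating'").mean_movement_mm
        # rolling median blurs the 2 boundary windows; tolerance covers it
        assert cheek_eat.iloc[0] == pytest.approx(0.2, rel=0.02)

    def test_participant_missing_activity_excluded(self):
        full = _constant_item(
            "P1", [("eating", 4.0, 0.1), ("speaking", 4.0, 0.05), ("clenching", 4.0, 0.01)]
        )
        partial = _constant_item("P2", [("eating", 4.0, 0.1), ("speaking", 4.0, 0.05)])
        with pytest.warns(UserWarning, match="P2"):
            means = participant_activity_means([full, partial])
        assert set(means.participant_id) == {"P1"}


def test_paired_tests_on_ordered_cohort():
    rng = np.random.default_rng(7)
    items = []
    for i in range(10):
        mult = float(np.exp(rng.normal(0, 0.3)))
        items.append(
            _constant_item(
                f"P{i}",
                [
                    ("eating", 2.0, 0.113 * mult),
                    ("speaking", 2.0, 0.036 * mult),
                    ("clenching", 2.0, 0.008 * mult),
                ],
            )
        )
    results = paired_activity_tests(participant_activity_means(items))
    assert len(results) == 6
    assert all(r.reject for r in results)
    assert all(r.p_adjusted == pytest.approx(min(1.0, 6 * r.p_raw)) for r in results)
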