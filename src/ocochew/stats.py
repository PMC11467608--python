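"""Paired statistical comparison of facial-activity movement amplitudes.

Per participant and facial region (cheek, temple), the mean of the smoothed
combined left+right magnitude signal is computed over all samples annotated
with each activity (eating, speaking, clenching). Activity pairs are then
compared with two-sided Wilcoxon signed-rank tests and Bonferroni-adjusted
over the 6 comparisons (2 regions x 3 pairs).

The Wilcoxon implementation drops zero differences (Wilcoxon's treatment),
assigns midranks to ties, uses the exact null distribution of W+ for
n <= 25 (a dynamic-programming convolution over rank inclusion), and a
normal approximation with tie correction and continuity correction for
larger n.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as scipy_stats


from .errors import DataError
from .preprocess import region_magnitude_signals
from .simulate import CohortItem

__all__ = [
    "ACTIVITIES",
    "REGIONS",
    "PairedTestResult",
    "participant_activity_means",
    "wilcoxon_signed_rank",
    "bonferroni_adjust",
    "significance_annotation",
    "paired_activity_tests",
]

ACTIVITIES = ("eating", "speaking", "clenching")
REGIONS = ("cheek", "temple")
EXACT_N_MAX = 25


@dataclass(frozen=True)
class PairedTestResult:
    activity_a: str
    activity_b: str
    region: str
    statistic: float
    p_raw: float
    p_adjusted: float
    annotation: str
    reject: bool


def participant_activity_means(
    dataset: Sequence[CohortItem], smooth_samples: int = 15
) -> pd.DataFrame:
    """Tidy table of per-participant mean movement per region and activity.

    Means are pooled over all annotated samples of the activity across a
    participant's recordings. Participants missing any of the three
    activities are excluded (with a warning column left implicit: they are
    simply absent from the table).
    """
    rows = []
    for item in dataset:
        rec, track = item.recording, item.annotations
        signals = region_magnitude_signals(rec, smooth_samples=smooth_samples)
        labels = track.labels_for_samples(rec.times_s)
        for region in REGIONS:
            sig = signals[region]
            for activity in ACTIVITIES:
                mask = labels == activity
                if mask.any():
                    rows.append(
                        {
                            "participant_id": rec.participant_id,
                            "region": region,
                            "activity": activity,
                            "mean_movement_mm": float(sig[mask].mean()),
                            "n_samples": int(mask.sum()),
                        }
                    )
    df = pd.DataFrame(rows)
    if df.empty:
        raise DataError("no annotated activity samples in dataset")
    # pool across recordings of the same participant, weighted by samples
    df = (
        df.groupby(["participant_id", "region", "activity"], as_index=False)
        .apply(
            lambda g: pd.Series(
                {
                    "mean_movement_mm": np.average(g.mean_movement_mm, weights=g.n_samples),
                    "n_samples": g.n_samples.sum(),
                }
            ),
            include_groups=False,
        )
        .reset_index(drop=True)
    )
    # keep only participants with all three activities (per region they match)
    counts = df.groupby("participant_id")["activity"].nunique()
    complete = counts[counts == len(ACTIVITIES)].index
    dropped = set(counts.index) - set(complete)
    if dropped:
        import warnings

        warnings.warn(f"excluding participants missing an activity: {sorted(dropped)}")
    return df[df.participant_id.isin(complete)].reset_index(drop=True)


def _signed_rank_statistic(d: np.ndarray) -> tuple[float, np.ndarray]:
    """W+ (sum of ranks of positive differences) and the midranks of |d|."""
    ranks = scipy_stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    return w_plus, ranks


def _exact_two_sided_p(w_plus: float, ranks: np.ndarray) -> float:
    """Exact two-sided p over the 2^n equiprobable sign assignments.

    Midranks are multiples of 1/2, so doubling gives an integer-support
    distribution computed by convolution: each rank independently joins W+
    with probability 1/2.
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2.0 * w_plus))
    cdf = counts[: w2 + 1].sum()
    sf = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(cdf, sf)))


def _normal_two_sided_p(w_plus: float, ranks: np.ndarray) -> float:
    n = len(ranks)
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction: subtract sum(t^3 - t)/48 over tie groups
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= float(((tie_counts**3 - tie_counts) / 48.0).sum())
    if var <= 0:
        raise DataError("degenerate variance in Wilcoxon normal approximation")
    # continuity correction: shrink |W - mean| by 0.5
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
    return float(min(1.0, 2.0 * scipy_stats.norm.sf(abs(z))))


def wilcoxon_signed_rank(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test.

    Returns ``(W, p)`` where W = min(W+, W-), the smaller of the positive-
    and negative-difference rank sums of a - b after dropping zero
    differences (the conventional reported statistic).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DataError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        raise DataError("all paired differences are zero")
    if d.size < 5:
        raise DataError(f"need >= 5 non-zero differences, got {d.size}")
    w_plus, ranks = _signed_rank_statistic(d)
    if d.size <= EXACT_N_MAX:
        p = _exact_two_sided_p(w_plus, ranks)
    else:
        p = _normal_two_sided_p(w_plus, ranks)
    w = min(w_plus, float(ranks.sum()) - w_plus)
    return w, p


def bonferroni_adjust(
    p_values: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni: p_adj = min(1, m * p); reject iff p_adj < alpha."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise DataError("p-values must lie in [0, 1]")
    adjusted = np.minimum(1.0, len(p) * p)
    return adjusted, adjusted < alpha


def significance_annotation(p_adjusted: float) -> str:
    """Conventional significance stars: * <.05, ** <.01, *** <.001, **** <=.0001."""
    if not 0 <= p_adjusted <= 1:
        raise DataError("p must lie in [0, 1]")
    if p_adjusted <= 1e-4:
        return "****"
    if p_adjusted < 1e-3:
        return "***"
    if p_adjusted < 1e-2:
        return "**"
    if p_adjusted < 5e-2:
        return "*"
    return "ns"


def paired_activity_tests(
    means: pd.DataFrame, alpha: float = 0.05
) -> list[PairedTestResult]:
    """All 6 region x activity-pair Wilcoxon tests with Bonferroni adjustment."""
    comparisons = []
    stats_p = []
    wide = means.pivot_table(
        index="participant_id", columns=["region", "activity"], values="mean_movement_mm"
    )
    for region in REGIONS:
        for act_a, act_b in itertools.combinations(ACTIVITIES, 2):
            a = wide[(region, act_a)].to_numpy()
            b = wide[(region, act_b)].to_numpy()
            w, p = wilcoxon_signed_rank(a, b)
            comparisons.append((act_a, act_b, region, w))
            stats_p.append(p)
    adjusted, reject = bonferroni_adjust(stats_p, alpha=alpha)
    return [
        PairedTestResult(
            activity_a=a,
            activity_b=b,
            region=r,
            statistic=w,
            p_raw=p,
            p_adjusted=float(padj),
            annotation=significance_annotation(float(padj)),
            reject=bool(rej),
        )
        for (a, b, r, w), p, padj, rej in zip(comparisons, stats_p, adjusted, reject)
    ]
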