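"""Kinetic change-point segmentation of piecewise-linear time series.

Single-molecule traces here are well described by sequences of linear
segments (constant extension, steady compaction, steady relaxation).
The detector fits two independent least-squares lines over every
admissible split of the series and keeps the split minimizing the total
sum of squared errors; an F-test against the single-line null decides
whether the split is statistically warranted.  Recursive binary
splitting with the same test yields a full segment table.

The scan is exact (it equals a brute-force double regression at every
split) but runs in O(n) per scan using cumulative sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class ChangePointError(ValueError):
    pass


@dataclass(frozen=True)
class LinearSegment:
    t_start: float
    t_end: float
    slope: float
    intercept: float
    resid_sd: float
    n_points: int


@dataclass(frozen=True)
class ChangePointResult:
    """Optimal two-segment decomposition of a series.

    ``t_star`` is the time of the first point of the right segment;
    ``significance`` is the F-test p-value of the two-line model against
    the single-line null (small = confident split).
    """

    t_star: float
    split_index: int
    left: LinearSegment
    right: LinearSegment
    significance: float
    sse_two: float
    sse_one: float


def _prefix_stats(t: np.ndarray, y: np.ndarray):
    """Prefix sums enabling O(1) OLS line fits on any prefix/suffix."""
    one = np.concatenate(([0.0], np.cumsum(np.ones_like(t))))
    st = np.concatenate(([0.0], np.cumsum(t)))
    sy = np.concatenate(([0.0], np.cumsum(y)))
    stt = np.concatenate(([0.0], np.cumsum(t * t)))
    sty = np.concatenate(([0.0], np.cumsum(t * y)))
    syy = np.concatenate(([0.0], np.cumsum(y * y)))
    return one, st, sy, stt, sty, syy


def _range_fit(prefix, i: int, j: int):
    """OLS line fit and SSE over the half-open index range [i, j)."""
    one, st, sy, stt, sty, syy = prefix
    n = one[j] - one[i]
    s_t = st[j] - st[i]
    s_y = sy[j] - sy[i]
    s_tt = stt[j] - stt[i]
    s_ty = sty[j] - sty[i]
    s_yy = syy[j] - syy[i]
    denom = n * s_tt - s_t * s_t
    if denom <= 0:  # degenerate abscissa (repeated t)
        slope = 0.0
        intercept = s_y / n
        sse = s_yy - s_y * s_y / n
    else:
        slope = (n * s_ty - s_t * s_y) / denom
        intercept = (s_y - slope * s_t) / n
        sse = s_yy - intercept * s_y - slope * s_ty
    return slope, intercept, max(sse, 0.0)


def _range_sse_vec(prefix, i: np.ndarray, j: np.ndarray) -> np.ndarray:
    """Vectorized SSE of OLS line fits over index ranges [i, j)."""
    one, st, sy, stt, sty, syy = prefix
    n = one[j] - one[i]
    s_t = st[j] - st[i]
    s_y = sy[j] - sy[i]
    s_tt = stt[j] - stt[i]
    s_ty = sty[j] - sty[i]
    s_yy = syy[j] - syy[i]
    denom = n * s_tt - s_t * s_t
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(denom > 0, (n * s_ty - s_t * s_y) / np.where(denom > 0, denom, 1.0), 0.0)
        intercept = (s_y - slope * s_t) / n
        sse = s_yy - intercept * s_y - slope * s_ty
    return np.maximum(sse, 0.0)


def _segment_of(t, prefix, i, j) -> LinearSegment:
    slope, intercept, sse = _range_fit(prefix, i, j)
    n = j - i
    dof = max(n - 2, 1)
    return LinearSegment(
        t_start=float(t[i]),
        t_end=float(t[j - 1]),
        slope=float(slope),
        intercept=float(intercept),
        resid_sd=float(np.sqrt(sse / dof)),
        n_points=n,
    )


def fit_single_changepoint(t, y, min_pts: int = 3) -> ChangePointResult:
    """Optimal single change point by exhaustive SSE minimization.

    Every split index k with at least ``min_pts`` points on each side is
    scored by the summed SSE of independent left/right line fits; the
    minimum wins, ties broken by the earliest split.  Significance is
    the p-value of an F-test comparing the 4-parameter two-line model
    with the 2-parameter single line.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ChangePointError("t and y must be 1-D arrays of equal length")
    n = len(t)
    if n < 2 * min_pts:
        raise ChangePointError(f"need at least {2 * min_pts} points, got {n}")

    prefix = _prefix_stats(t, y)
    ks = np.arange(min_pts, n - min_pts + 1)
    sse_left = _range_sse_vec(prefix, np.zeros_like(ks), ks)
    sse_right = _range_sse_vec(prefix, ks, np.full_like(ks, n))
    total = sse_left + sse_right
    best_k = int(ks[np.argmin(total)])  # argmin keeps the earliest tie
    best_sse = float(total.min())

    left = _segment_of(t, prefix, 0, best_k)
    right = _segment_of(t, prefix, best_k, n)
    sse_one = _range_fit(prefix, 0, n)[2]
    sse_two = best_sse

    # SSE below the float cancellation floor of the prefix sums is zero
    tol = float(prefix[5][-1]) * 1e-12
    df2 = n - 4
    if df2 <= 0 or sse_two <= tol:
        pval = 0.0 if sse_one > max(sse_two, tol) else 1.0
    else:
        f_stat = ((sse_one - sse_two) / 2.0) / (sse_two / df2)
        # Bonferroni over the scanned splits: the F statistic was maximized
        # over len(ks) candidate change points, so the raw tail probability
        # is anti-conservative by up to that factor
        pval = float(min(1.0, stats.f.sf(f_stat, 2, df2) * len(ks)))
    return ChangePointResult(
        t_star=float(t[best_k]),
        split_index=best_k,
        left=left,
        right=right,
        significance=pval,
        sse_two=float(sse_two),
        sse_one=float(sse_one),
    )


def _fixed_split_pvalue(prefix, i: int, k: int, j: int) -> float:
    """F-test p-value of a split at a *given* index (no selection penalty)."""
    one, st, sy, stt, sty, syy = prefix
    sse_one = _range_fit(prefix, i, j)[2]
    sse_two = _range_fit(prefix, i, k)[2] + _range_fit(prefix, k, j)[2]
    n = j - i
    tol = (syy[j] - syy[i]) * 1e-12
    df2 = n - 4
    if df2 <= 0 or sse_two <= tol:
        return 0.0 if sse_one > max(sse_two, tol) else 1.0
    f_stat = ((sse_one - sse_two) / 2.0) / (sse_two / df2)
    return float(stats.f.sf(f_stat, 2, df2))


def segment_trace(t, y, confidence: float = 0.99, min_pts: int = 3) -> list[LinearSegment]:
    """Recursive binary change-point segmentation with a merge pass.

    Splitting: a chunk is divided at its optimal change point whenever
    the (selection-corrected) F-test p-value falls below
    ``1 - confidence``, recursively.  Because the optimal single split
    of a multi-kink chunk need not land on a kink, a bottom-up merge
    pass then joins adjacent segments whose shared boundary is not a
    significant change point.  Returned segments tile the series in
    time order.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    alpha = 1.0 - confidence
    prefix = _prefix_stats(t, y)

    bounds: list[int] = []

    def recurse(i: int, j: int) -> None:
        if j - i >= 2 * min_pts:
            res = fit_single_changepoint(t[i:j], y[i:j], min_pts=min_pts)
            if res.significance < alpha:
                k = i + res.split_index
                recurse(i, k)
                recurse(k, j)
                return
        bounds.append(i)

    recurse(0, len(t))
    bounds.append(len(t))
    bounds.sort()

    # merge adjacent segments across non-significant boundaries,
    # least significant first
    while len(bounds) > 2:
        pvals = [_fixed_split_pvalue(prefix, bounds[m - 1], bounds[m], bounds[m + 1])
                 for m in range(1, len(bounds) - 1)]
        worst = int(np.argmax(pvals))
        if pvals[worst] < alpha:
            break
        del bounds[worst + 1]

    return [_segment_of(t, prefix, i, j) for i, j in zip(bounds, bounds[1:])]


def segments_to_table(segments: list[LinearSegment]):
    """Segment list as archive segment-table rows."""
    import pandas as pd

    return pd.DataFrame(
        [(s.t_start, s.t_end, s.slope, s.intercept, s.resid_sd) for s in segments],
        columns=["t_start", "t_end", "slope", "intercept", "resid_sd"],
    )
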