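"""Unsupervised 1-D threshold selection and separation quality.

The scoring pipeline places thresholds on 1-D sample distributions twice:
a two-cluster k-means threshold on smoothed spindle power (and on
theta/delta ratio bins in the standard baseline scorer), and an Otsu
threshold on the smoothed cortical theta/delta ratio when no hippocampal
channel is available.  Both are deterministic here.

In one dimension the two-cluster k-means optimum is a contiguous split of
the sorted values, so instead of Lloyd iterations from a random start we
solve it exactly: scan every split point with prefix sums and keep the one
minimizing within-group sum of squares.  This is equivalent to running
Lloyd's algorithm to its global optimum and removes all run-to-run
nondeterminism.

Separation quality is summarized by the effectiveness metric

    m = 1 - sigma_i / sigma_tot

where ``sigma_i`` is the pooled (group-size-weighted) intra-group variance
and ``sigma_tot`` the variance of all values.  By the law of total
variance m lies in [0, 1]: m = 1 when both groups are internally constant
and m = 0 when the group means coincide.  Population (not sample)
variances are used throughout so that m = 1 is attainable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDistributionError, InvalidParameterError
from .intervals import IntervalSet
from .signals import SignalTrace, gaussian_smooth

__all__ = [
    "ThresholdResult",
    "kmeans2_threshold",
    "otsu_threshold",
    "separation_effectiveness",
    "smoothing_window_sweep",
]


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of a two-group 1-D split.

    Attributes
    ----------
    threshold
        Decision boundary in signal units; values ``> threshold`` belong
        to the high group.
    group_means
        (low-group mean, high-group mean).
    effectiveness
        The separation metric m in [0, 1].
    """

    threshold: float
    group_means: tuple[float, float]
    effectiveness: float

    def __post_init__(self) -> None:
        lo, hi = self.group_means
        if not (lo < hi):
            raise InvalidParameterError("group means must satisfy low < high")
        if not (lo < self.threshold <= hi):
            raise InvalidParameterError(
                "threshold must lie in (low mean, high mean]"
            )


def _as_clean_array(values: Sequence[float]) -> np.ndarray:
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise InvalidParameterError("need at least 2 values")
    if not np.all(np.isfinite(v)):
        raise InvalidParameterError("values must be finite")
    if np.ptp(v) <= 1e-9 * max(1e-300, np.abs(v).max()):
        raise DegenerateDistributionError("all values identical; nothing to split")
    return v


def separation_effectiveness(
    values: Sequence[float], assignment: Sequence[int]
) -> float:
    """Effectiveness m = 1 − σ_i/σ_tot of a binary split of ``values``.

    ``assignment`` holds binary labels (0/1 or booleans); both groups must
    be non-empty and the overall variance must be positive.
    """
    v = np.asarray(values, dtype=float).ravel()
    a = np.asarray(assignment).ravel().astype(bool)
    if v.size != a.size:
        raise InvalidParameterError("values and assignment lengths differ")
    n0, n1 = int((~a).sum()), int(a.sum())
    if n0 == 0 or n1 == 0:
        raise InvalidParameterError("both groups must be non-empty")
    sigma_tot = float(np.var(v))
    if sigma_tot == 0:
        raise DegenerateDistributionError("total variance is zero")
    sigma_i = (n0 * np.var(v[~a]) + n1 * np.var(v[a])) / v.size
    return float(1.0 - sigma_i / sigma_tot)


def kmeans2_threshold(values: Sequence[float]) -> ThresholdResult:
    """Deterministic two-cluster 1-D k-means threshold.

    Finds the split of the sorted values minimizing the within-group sum
    of squares (the exact 1-D 2-means optimum) and returns the midpoint of
    the two group means as the threshold.  At the optimum every value is
    assigned to its nearest group mean, matching the k-means fixed point.
    """
    v = np.sort(_as_clean_array(values))
    n = v.size
    csum = np.cumsum(v)
    csq = np.cumsum(v * v)
    k = np.arange(1, n)  # low group sizes
    lo_sum, lo_sq = csum[:-1], csq[:-1]
    hi_sum, hi_sq = csum[-1] - lo_sum, csq[-1] - lo_sq
    sse = (lo_sq - lo_sum**2 / k) + (hi_sq - hi_sum**2 / (n - k))
    best = int(np.argmin(sse))
    mean_lo = lo_sum[best] / (best + 1)
    mean_hi = hi_sum[best] / (n - best - 1)
    thr = 0.5 * (mean_lo + mean_hi)
    m = separation_effectiveness(v, v > thr)
    return ThresholdResult(float(thr), (float(mean_lo), float(mean_hi)), m)


def otsu_threshold(values: Sequence[float], n_bins: int = 256) -> ThresholdResult:
    """Histogram threshold maximizing between-class variance (Otsu).

    The candidate thresholds are the interior histogram bin edges; the one
    maximizing between-class variance of the induced two-group split is
    returned.  When several edges attain the maximum — which happens
    whenever the modes are separated by empty bins — the middle maximizer
    is taken (the usual convention of reference implementations).
    Deterministic for fixed input and ``n_bins``.  Group means and
    effectiveness are computed from the actual values, not the histogram.
    """
    if n_bins < 2:
        raise InvalidParameterError(f"n_bins must be >= 2, got {n_bins}")
    v = _as_clean_array(values)
    counts, edges = np.histogram(v, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = counts.astype(float)
    total = w.sum()
    cw = np.cumsum(w)
    cmean = np.cumsum(w * centers)
    # between-class variance at each interior edge (split after bin i)
    w0 = cw[:-1]
    w1 = total - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cmean[:-1] / w0
        mu1 = (cmean[-1] - cmean[:-1]) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[(w0 == 0) | (w1 == 0)] = -np.inf
    # splits across an empty-bin plateau tie up to rounding; take the middle
    maximizers = np.flatnonzero(between >= between.max() * (1 - 1e-12))
    best = int(round(float(np.mean(maximizers))))
    thr = float(edges[best + 1])
    high = v > thr
    if not high.any() or high.all():  # threshold at an empty tail edge
        raise DegenerateDistributionError("Otsu split left one group empty")
    mean_lo = float(v[~high].mean())
    mean_hi = float(v[high].mean())
    m = separation_effectiveness(v, high)
    return ThresholdResult(thr, (mean_lo, mean_hi), m)


def smoothing_window_sweep(
    envelope_raw: SignalTrace,
    immobility: IntervalSet,
    windows: Sequence[float],
    subsample_interval: float = 0.5,
) -> pd.DataFrame:
    """Separation effectiveness of the spindle-power split per smoothing window.

    For each window: smooth the raw envelope, restrict to immobility
    samples (subsampled to one value per ``subsample_interval`` seconds to
    decorrelate), split with the k-means threshold, and record m.  Rows
    appear in the input window order; windows for which the restricted
    distribution is degenerate get ``NaN`` with an error note.
    """
    if len(list(windows)) < 1:
        raise InvalidParameterError("need at least one window")
    mask = immobility.rasterize(envelope_raw.rate, len(envelope_raw))
    step = max(1, int(round(subsample_interval * envelope_raw.rate)))
    rows = []
    for w in windows:
        smoothed = gaussian_smooth(envelope_raw, w)
        vals = smoothed.samples[mask][::step]
        try:
            res = kmeans2_threshold(vals)
            rows.append({"window_s": w, "m": res.effectiveness, "note": ""})
        except (DegenerateDistributionError, InvalidParameterError) as exc:
            rows.append({"window_s": w, "m": np.nan, "note": str(exc)})
    return pd.DataFrame(rows)
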