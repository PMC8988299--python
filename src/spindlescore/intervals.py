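"""Interval algebra for behavioral epochs.

Every detector in the scoring pipeline manipulates sets of time intervals:
immobility bouts, slow-wave-sleep periods, REM periods, and so on.  This
module provides the single epoch currency they all share — an ordered,
pairwise-disjoint set of half-open intervals ``[start, end)`` measured in
seconds from recording start — together with the handful of operations the
detectors are built from: construction from boolean sample masks,
gap-closing (ignore brief movements), minimum-duration filtering, set
subtraction, and "follows/precedes within" temporal relations.

Conventions
-----------
* Intervals are half-open, ``[start, end)``, so durations add exactly and a
  boolean mask round-trips through :meth:`IntervalSet.from_mask` /
  :meth:`IntervalSet.rasterize` without off-by-one ambiguity.
* Touching intervals (``[0, 2), [2, 3)``) are merged on construction.
* Gap comparisons are strict (a gap is closed when it is ``< max_gap``);
  duration comparisons keep an interval when its duration is ``>= min``.
"""

from __future__ import annotations

from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

__all__ = ["Interval", "IntervalSet", "read_intervals_tsv", "write_intervals_tsv"]


class Interval(NamedTuple):
    """Half-open time interval ``[start, end)`` in seconds."""

    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


class IntervalSet:
    """Ordered, pairwise-disjoint set of half-open intervals in seconds.

    The constructor sorts its input, validates it (finite, non-negative
    times, ``start < end``) and merges any overlapping or touching
    intervals, so every ``IntervalSet`` in circulation satisfies the class
    invariants by construction.
    """

    __slots__ = ("_data",)

    def __init__(self, intervals: Iterable[Sequence[float]] = ()) -> None:
        arr = np.asarray(list(intervals), dtype=float)
        if arr.size == 0:
            self._data = np.empty((0, 2), dtype=float)
            return
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise InvalidParameterError(
                "intervals must be an iterable of (start, end) pairs"
            )
        if not np.all(np.isfinite(arr)):
            raise InvalidParameterError("interval bounds must be finite")
        if np.any(arr < 0):
            raise InvalidParameterError("interval bounds must be non-negative")
        if np.any(arr[:, 0] >= arr[:, 1]):
            raise InvalidParameterError("each interval must satisfy start < end")
        arr = arr[np.argsort(arr[:, 0], kind="stable")]
        # merge overlapping or touching neighbours
        merged = [arr[0].copy()]
        for start, end in arr[1:]:
            if start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append(np.array([start, end]))
        self._data = np.vstack(merged)

    # -- basic container protocol -------------------------------------------------

    def __len__(self) -> int:
        return self._data.shape[0]

    def __iter__(self) -> Iterator[Interval]:
        for start, end in self._data:
            yield Interval(float(start), float(end))

    def __getitem__(self, i: int) -> Interval:
        start, end = self._data[i]
        return Interval(float(start), float(end))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._data.shape == other._data.shape and np.array_equal(
            self._data, other._data
        )

    def __repr__(self) -> str:
        inner = ", ".join(f"[{s:g}, {e:g})" for s, e in self._data[:6])
        if len(self) > 6:
            inner += f", … ({len(self)} total)"
        return f"IntervalSet({inner})"

    @property
    def starts(self) -> np.ndarray:
        return self._data[:, 0].copy()

    @property
    def ends(self) -> np.ndarray:
        return self._data[:, 1].copy()

    def as_array(self) -> np.ndarray:
        """Return an ``(n, 2)`` float array of (start, end) rows."""
        return self._data.copy()

    @property
    def durations(self) -> np.ndarray:
        return self._data[:, 1] - self._data[:, 0]

    @property
    def total_duration(self) -> float:
        return float(self.durations.sum()) if len(self) else 0.0

    def is_empty(self) -> bool:
        return len(self) == 0

    # -- construction -------------------------------------------------------------

    @classmethod
    def from_mask(cls, mask: Sequence[bool], rate: float) -> "IntervalSet":
        """Convert maximal runs of true samples into half-open intervals.

        Sample ``i`` covers ``[i/rate, (i+1)/rate)``; a run of true samples
        ``i..j`` becomes the interval ``[i/rate, (j+1)/rate)``.
        """
        if rate <= 0:
            raise InvalidParameterError(f"rate must be positive, got {rate}")
        m = np.asarray(mask, dtype=bool)
        if m.size == 0:
            raise InvalidParameterError("mask must be non-empty")
        padded = np.concatenate(([False], m, [False])).astype(np.int8)
        diff = np.diff(padded)
        run_starts = np.flatnonzero(diff == 1)
        run_ends = np.flatnonzero(diff == -1)  # exclusive sample index
        return cls(np.column_stack((run_starts / rate, run_ends / rate)))

    def rasterize(self, rate: float, n_samples: int) -> np.ndarray:
        """Boolean mask of length ``n_samples``: sample ``i`` is true when its
        start time ``i/rate`` falls inside a member interval.

        Exact inverse of :meth:`from_mask` for grid-aligned interval sets.
        """
        if rate <= 0:
            raise InvalidParameterError(f"rate must be positive, got {rate}")
        t = np.arange(n_samples) / rate
        idx = np.searchsorted(self._data[:, 0], t, side="right") - 1
        mask = idx >= 0
        mask[mask] = t[mask] < self._data[idx[mask], 1]
        return mask

    # -- core algebra -------------------------------------------------------------

    def close_gaps(self, max_gap: float) -> "IntervalSet":
        """Merge consecutive intervals separated by a gap strictly below
        ``max_gap`` seconds (brief interruptions are ignored)."""
        if max_gap < 0:
            raise InvalidParameterError(f"max_gap must be >= 0, got {max_gap}")
        if len(self) < 2 or max_gap == 0:
            return self._copy()
        merged = [self._data[0].copy()]
        for start, end in self._data[1:]:
            if start - merged[-1][1] < max_gap:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append(np.array([start, end]))
        return IntervalSet(merged)

    def drop_short(self, min_duration: float) -> "IntervalSet":
        """Remove intervals shorter than ``min_duration`` seconds.

        Intervals with duration exactly ``min_duration`` are kept.  No
        interval is altered, only removed.
        """
        if min_duration < 0:
            raise InvalidParameterError(
                f"min_duration must be >= 0, got {min_duration}"
            )
        keep = self.durations >= min_duration
        return IntervalSet(self._data[keep])

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        """Time covered by ``self`` but not by ``other``."""
        if other.is_empty() or self.is_empty():
            return self._copy()
        pieces: list[tuple[float, float]] = []
        ob = other._data
        for start, end in self._data:
            cursor = start
            # intervals of other that can overlap [start, end)
            lo = np.searchsorted(ob[:, 1], start, side="right")
            hi = np.searchsorted(ob[:, 0], end, side="left")
            for bs, be in ob[lo:hi]:
                if bs > cursor:
                    pieces.append((cursor, bs))
                cursor = max(cursor, be)
                if cursor >= end:
                    break
            if cursor < end:
                pieces.append((cursor, end))
        return IntervalSet(pieces)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        """Time covered by both sets."""
        if self.is_empty() or other.is_empty():
            return IntervalSet()
        pieces: list[tuple[float, float]] = []
        ob = other._data
        for start, end in self._data:
            lo = np.searchsorted(ob[:, 1], start, side="right")
            hi = np.searchsorted(ob[:, 0], end, side="left")
            for bs, be in ob[lo:hi]:
                s, e = max(start, bs), min(end, be)
                if s < e:
                    pieces.append((s, e))
        return IntervalSet(pieces)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet(np.vstack((self._data, other._data)))

    def follows_within(
        self,
        anchors: "IntervalSet",
        max_delay: float,
        direction: str = "after",
    ) -> "IntervalSet":
        """Subset of ``self`` in a temporal relation to some anchor interval.

        direction="after"
            keep candidates whose start lies within ``max_delay`` seconds
            after the end of some anchor (e.g. REM periods must closely
            follow slow-wave sleep).
        direction="before"
            keep candidates whose end lies within ``max_delay`` seconds
            before the start of some anchor (e.g. quiet wakefulness
            precedes sleep onset).

        Overlap with an anchor counts as delay zero.  The comparison is
        inclusive (``delay <= max_delay``).  A candidate related to several
        anchors is retained once.
        """
        if max_delay < 0:
            raise InvalidParameterError(f"max_delay must be >= 0, got {max_delay}")
        if direction not in ("after", "before"):
            raise InvalidParameterError(
                f"direction must be 'after' or 'before', got {direction!r}"
            )
        if self.is_empty() or anchors.is_empty():
            return IntervalSet()
        a = anchors._data
        keep = np.zeros(len(self), dtype=bool)
        for i, (cs, ce) in enumerate(self._data):
            overlap = np.any((a[:, 0] < ce) & (cs < a[:, 1]))
            if overlap:
                keep[i] = True
                continue
            if direction == "after":
                prior = a[:, 1] <= cs
                if np.any(prior):
                    keep[i] = (cs - a[prior, 1].max()) <= max_delay
            else:
                later = a[:, 0] >= ce
                if np.any(later):
                    keep[i] = (a[later, 0].min() - ce) <= max_delay
        return IntervalSet(self._data[keep])

    # -- helpers ------------------------------------------------------------------

    def _copy(self) -> "IntervalSet":
        out = IntervalSet.__new__(IntervalSet)
        out._data = self._data.copy()
        return out


def write_intervals_tsv(path, labeled_sets: dict[str, IntervalSet]) -> None:
    """Write labeled interval sets as a TSV with columns start_s, end_s, label.

    Rows are sorted by start time; times are printed with 4 decimal places.
    """
    rows = []
    for label, ivs in labeled_sets.items():
        for iv in ivs:
            rows.append((iv.start, iv.end, label))
    rows.sort()
    df = pd.DataFrame(rows, columns=["start_s", "end_s", "label"])
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_intervals_tsv(path) -> dict[str, IntervalSet]:
    """Inverse of :func:`write_intervals_tsv`."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, IntervalSet] = {}
    for label, grp in df.groupby("label", sort=False):
        out[str(label)] = IntervalSet(grp[["start_s", "end_s"]].to_numpy())
    return out
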