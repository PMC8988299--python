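"""Behavioral-state classifiers.

Two scorers are provided:

* :func:`score_session` — the spindle-power pipeline.  Immobility is
  detected from the angular-speed trace; immobility with high smoothed
  spindle-band (9–17 Hz) power is slow-wave sleep (SWS); theta/delta-
  dominated immobility closely following SWS is REM; immobility shortly
  preceding SWS onset is quiet wakefulness; everything else is freezing.
  Because each detector operates on the remainder left by its
  predecessors, the four output states are pairwise disjoint by
  construction.

* :func:`standard_score` — the classic baseline in which freezing
  (immobility > 1.5 s) and sleep (immobility > 60 s, split into SWS/REM
  by a k-means threshold on the theta/delta ratio) are detected
  independently.  On sessions containing freezing the two labels overlap
  heavily: the 4 Hz freezing rhythm sits inside the delta band, so long
  freezing bouts look exactly like SWS to a theta/delta scorer.  The
  baseline exists to demonstrate this failure mode.

All stated defaults (30 s / 1 s SWS bout and gap limits, theta/delta
threshold of 1 for hippocampal recordings, 30 s REM-after-SWS delay,
2 min quiet-wake lead, 2 s / 0.2 s freezing bout and gap limits, 14 s and
8 s smoothing windows) live in :class:`ScoringParams`.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np

from .errors import AlignmentError, DegenerateDistributionError, InvalidParameterError
from .intervals import IntervalSet, write_intervals_tsv
from .signals import (
    DELTA_BAND,
    SPINDLE_BAND,
    THETA_BAND,
    BandDefinition,
    SignalTrace,
    band_power_ratio,
    bandpass,
    envelope,
    gaussian_smooth,
)
from .thresholds import ThresholdResult, kmeans2_threshold, otsu_threshold

__all__ = [
    "ScoringParams",
    "StateScoring",
    "StandardScoring",
    "detect_immobility",
    "detect_sws",
    "detect_rem",
    "detect_quiet_wake",
    "detect_freezing",
    "score_session",
    "standard_score",
    "bin_labels",
]

logger = logging.getLogger("spindlescore")

STATE_LABELS = ("sws", "rem", "quiet_wake", "freezing")


@dataclass(frozen=True)
class ScoringParams:
    """Every tunable of both scorers, with the published defaults."""

    # immobility
    speed_threshold: float | None = None  # None -> k-means on log speed
    immobility_min_duration: float = 1.5
    immobility_max_gap: float = 0.2
    # bands
    spindle_band: BandDefinition = SPINDLE_BAND
    theta_band: BandDefinition = THETA_BAND
    delta_band: BandDefinition = DELTA_BAND
    # SWS
    spindle_smooth_window: float = 14.0
    sws_min_duration: float = 30.0
    sws_max_gap: float = 1.0
    sws_effectiveness_floor: float = 0.75
    threshold_scope: str = "immobility"  # or "session"
    threshold_subsample: float = 0.5  # s between samples entering k-means
    # REM
    rem_ratio_threshold: float = 1.0  # hippocampal mode
    cortical_ratio_smooth_window: float = 8.0
    rem_max_delay_after_sws: float = 30.0
    rem_min_duration: float = 5.0
    rem_chain: bool = False  # allow REM anchored to already-accepted REM
    ratio_bin: float = 1.0
    # quiet wakefulness
    quiet_wake_max_lead: float = 120.0
    # freezing
    freezing_min_duration: float = 2.0
    freezing_max_gap: float = 0.2
    # standard baseline
    standard_freezing_min_duration: float = 1.5
    standard_freezing_max_gap: float = 0.2
    standard_sleep_min_duration: float = 60.0
    standard_sleep_max_gap: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name.endswith(
                ("duration", "gap", "window", "lead", "delay_after_sws", "bin")
            ) and not (isinstance(v, (int, float)) and v >= 0):
                raise InvalidParameterError(f"{f.name} must be a non-negative number")
        if self.threshold_scope not in ("immobility", "session"):
            raise InvalidParameterError(
                "threshold_scope must be 'immobility' or 'session'"
            )

    def asdict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, BandDefinition) else v
        return out


@dataclass(frozen=True)
class StateScoring:
    """Labeled partition of immobility into the four behavioral states."""

    sws: IntervalSet
    rem: IntervalSet
    quiet_wake: IntervalSet
    freezing: IntervalSet
    immobility: IntervalSet
    diagnostics: dict = field(default_factory=dict)

    def states(self) -> dict[str, IntervalSet]:
        return {
            "sws": self.sws,
            "rem": self.rem,
            "quiet_wake": self.quiet_wake,
            "freezing": self.freezing,
        }

    def to_tsv(self, path) -> None:
        write_intervals_tsv(path, self.states())

    def write_diagnostics(self, path) -> None:
        with open(path, "w") as fh:
            for key, value in sorted(self.diagnostics.items()):
                fh.write(f"{key}\t{json.dumps(value)}\n")


@dataclass(frozen=True)
class StandardScoring:
    """Output of the baseline scorer; freezing and sleep may overlap."""

    freezing: IntervalSet
    sws: IntervalSet
    rem: IntervalSet
    sleep: IntervalSet
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# immobility
# ---------------------------------------------------------------------------


def estimate_speed_threshold(speed: SignalTrace) -> float:
    """Immobility/movement boundary as the k-means threshold of log speed."""
    eps = 1e-6
    res = kmeans2_threshold(np.log(np.abs(speed.samples) + eps))
    return float(np.exp(res.threshold))


def detect_immobility(speed: SignalTrace, p: ScoringParams) -> IntervalSet:
    """Maximal sub-threshold runs of the speed trace, with brief movements
    (gaps < ``immobility_max_gap``) ignored and bouts shorter than
    ``immobility_min_duration`` discarded."""
    thr = (
        p.speed_threshold
        if p.speed_threshold is not None
        else estimate_speed_threshold(speed)
    )
    mask = speed.samples < thr
    if not mask.any():
        return IntervalSet()
    return (
        IntervalSet.from_mask(mask, speed.rate)
        .close_gaps(p.immobility_max_gap)
        .drop_short(p.immobility_min_duration)
    )


# ---------------------------------------------------------------------------
# slow-wave sleep
# ---------------------------------------------------------------------------


def smoothed_spindle_power(cortical: SignalTrace, p: ScoringParams) -> SignalTrace:
    """Spindle-band Hilbert envelope smoothed with the 14 s Gaussian window."""
    return gaussian_smooth(
        envelope(bandpass(cortical, p.spindle_band)), p.spindle_smooth_window
    )


def detect_sws(
    cortical: SignalTrace, immobility: IntervalSet, p: ScoringParams
) -> tuple[IntervalSet, ThresholdResult | None]:
    """Immobility with supra-threshold smoothed spindle power.

    The threshold is the deterministic two-cluster k-means split of the
    smoothed-envelope samples during immobility (subsampled to one value
    per ``threshold_subsample`` seconds to decorrelate).  If the split is
    ineffective (m below ``sws_effectiveness_floor``) the session is
    declared sleep-free: an empty set is returned with a warning rather
    than thresholding noise.
    """
    if immobility.is_empty():
        return IntervalSet(), None
    smoothed = smoothed_spindle_power(cortical, p)
    if p.threshold_scope == "immobility":
        mask = immobility.rasterize(smoothed.rate, len(smoothed))
        pool = smoothed.samples[mask]
    else:
        pool = smoothed.samples
    step = max(1, int(round(p.threshold_subsample * smoothed.rate)))
    pool = pool[::step]
    try:
        result = kmeans2_threshold(pool)
    except (DegenerateDistributionError, InvalidParameterError) as exc:
        warnings.warn(f"no SWS detected: {exc}", stacklevel=2)
        return IntervalSet(), None
    if result.effectiveness < p.sws_effectiveness_floor:
        warnings.warn(
            "no SWS detected: spindle-power split effectiveness "
            f"m={result.effectiveness:.3f} below floor "
            f"{p.sws_effectiveness_floor}",
            stacklevel=2,
        )
        return IntervalSet(), result
    supra = IntervalSet.from_mask(smoothed.samples > result.threshold, smoothed.rate)
    # gap closing (movements < sws_max_gap are ignored) rescues bouts
    # fragmented by micro-movements before the duration filter; the final
    # intersection keeps the movement time itself out of the sleep label
    sws = (
        supra.intersect(immobility)
        .close_gaps(p.sws_max_gap)
        .drop_short(p.sws_min_duration)
        .intersect(immobility)
    )
    return sws, result


# ---------------------------------------------------------------------------
# REM
# ---------------------------------------------------------------------------


def detect_rem(
    lfp: SignalTrace,
    immobility: IntervalSet,
    sws: IntervalSet,
    p: ScoringParams,
    mode: str = "hpc",
) -> IntervalSet:
    """Theta/delta-dominated immobility closely following SWS.

    In "hpc" mode the hippocampal theta/delta ratio is compared with the
    fixed threshold (default 1).  In "cortical" mode the cortical ratio is
    first Gaussian-smoothed (8 s window) and the threshold is found with
    the Otsu method, because cortical theta/delta ratios run lower than
    hippocampal ones.  Candidate epochs are maximal runs of
    supra-threshold ``ratio_bin`` bins within immobility-minus-SWS, at
    least ``rem_min_duration`` long; only candidates starting within
    ``rem_max_delay_after_sws`` seconds after an SWS epoch (or overlapping
    one) are kept.  With no SWS anywhere, REM is empty by construction.
    """
    if mode not in ("hpc", "cortical"):
        raise InvalidParameterError(f"mode must be 'hpc' or 'cortical', got {mode!r}")
    if sws.is_empty() or immobility.is_empty():
        return IntervalSet()
    remaining = immobility.subtract(sws)
    if remaining.is_empty():
        return IntervalSet()
    ratio = band_power_ratio(lfp, p.theta_band, p.delta_band, p.ratio_bin)
    if mode == "hpc":
        threshold = p.rem_ratio_threshold
        values = ratio.samples
    else:
        smoothed = gaussian_smooth(ratio, p.cortical_ratio_smooth_window)
        values = smoothed.samples
        mask = remaining.rasterize(ratio.rate, len(values))
        finite = np.isfinite(values[mask])
        try:
            threshold = otsu_threshold(values[mask][finite]).threshold
        except (DegenerateDistributionError, InvalidParameterError) as exc:
            warnings.warn(f"no REM detected (cortical mode): {exc}", stacklevel=2)
            return IntervalSet()
    supra = values > threshold
    if not supra.any():
        return IntervalSet()
    candidates = (
        IntervalSet.from_mask(supra, ratio.rate)
        .intersect(remaining)
        .drop_short(p.rem_min_duration)
    )
    kept = candidates.follows_within(sws, p.rem_max_delay_after_sws, "after")
    if p.rem_chain:
        while True:
            anchors = sws.union(kept)
            wider = candidates.follows_within(
                anchors, p.rem_max_delay_after_sws, "after"
            )
            if len(wider) == len(kept):
                break
            kept = wider
    return kept


# ---------------------------------------------------------------------------
# quiet wakefulness and freezing
# ---------------------------------------------------------------------------


def detect_quiet_wake(
    immobility: IntervalSet,
    sws: IntervalSet,
    rem: IntervalSet,
    p: ScoringParams,
) -> IntervalSet:
    """Awake immobility shortly preceding sleep onset.

    From immobility minus (SWS ∪ REM), keep epochs ending within
    ``quiet_wake_max_lead`` seconds before some SWS start.  Anchoring uses
    SWS only: animals fall asleep from quiet wakefulness, not from REM.
    """
    if sws.is_empty():
        return IntervalSet()
    rest = immobility.subtract(sws.union(rem))
    return rest.follows_within(sws, p.quiet_wake_max_lead, "before")


def detect_freezing(
    immobility: IntervalSet,
    sws: IntervalSet,
    rem: IntervalSet,
    quiet_wake: IntervalSet,
    p: ScoringParams,
) -> IntervalSet:
    """All remaining immobility, with brief interruptions closed
    (< ``freezing_max_gap``) and bouts shorter than
    ``freezing_min_duration`` discarded.

    Closed gaps are brief movements and become part of the freezing bout
    (immobility detection closes the same gaps, so with the default
    parameters freezing stays inside detected immobility).
    """
    rest = immobility.subtract(sws.union(rem).union(quiet_wake))
    return rest.close_gaps(p.freezing_max_gap).drop_short(p.freezing_min_duration)


# ---------------------------------------------------------------------------
# full pipelines
# ---------------------------------------------------------------------------


def _check_alignment(traces: Sequence[SignalTrace], tolerance: float = 1.0) -> None:
    durations = [t.duration for t in traces]
    starts = [t.start_time for t in traces]
    if max(durations) - min(durations) > tolerance:
        raise AlignmentError(
            f"trace durations differ by more than {tolerance} s: {durations}"
        )
    if max(starts) - min(starts) > tolerance:
        raise AlignmentError(f"trace start times differ: {starts}")


def score_session(
    cortical: SignalTrace,
    hpc: SignalTrace | None,
    speed: SignalTrace,
    p: ScoringParams | None = None,
) -> StateScoring:
    """Run the full spindle-power pipeline on one session.

    Detector order is fixed — immobility → SWS → REM → quiet wakefulness →
    freezing — with each stage consuming the remainder left by the
    previous ones, which guarantees a zero-overlap partition.  REM mode is
    selected automatically: hippocampal theta/delta against the fixed
    threshold when an HPC trace is supplied, otherwise the smoothed
    cortical ratio against an Otsu threshold.
    """
    p = p or ScoringParams()
    traces = [cortical, speed] + ([hpc] if hpc is not None else [])
    _check_alignment(traces)

    speed_thr = (
        p.speed_threshold
        if p.speed_threshold is not None
        else estimate_speed_threshold(speed)
    )
    p_run = replace(p, speed_threshold=speed_thr)

    immobility = detect_immobility(speed, p_run)
    sws, sws_thr = detect_sws(cortical, immobility, p_run)
    mode = "hpc" if hpc is not None else "cortical"
    rem = detect_rem(hpc if hpc is not None else cortical, immobility, sws, p_run, mode)
    quiet_wake = detect_quiet_wake(immobility, sws, rem, p_run)
    freezing = detect_freezing(immobility, sws, rem, quiet_wake, p_run)

    diagnostics = {
        "speed_threshold": speed_thr,
        "rem_mode": mode,
        "immobility_total_s": immobility.total_duration,
        "sws_total_s": sws.total_duration,
        "rem_total_s": rem.total_duration,
        "quiet_wake_total_s": quiet_wake.total_duration,
        "freezing_total_s": freezing.total_duration,
        "params": p.asdict(),
    }
    if sws_thr is not None:
        diagnostics["sws_threshold"] = sws_thr.threshold
        diagnostics["sws_group_means"] = list(sws_thr.group_means)
        diagnostics["sws_effectiveness_m"] = sws_thr.effectiveness
    logger.info(
        "scored session: immobility %.1f s, sws %.1f s, rem %.1f s, "
        "quiet_wake %.1f s, freezing %.1f s",
        immobility.total_duration,
        sws.total_duration,
        rem.total_duration,
        quiet_wake.total_duration,
        freezing.total_duration,
    )
    return StateScoring(
        sws=sws,
        rem=rem,
        quiet_wake=quiet_wake,
        freezing=freezing,
        immobility=immobility,
        diagnostics=diagnostics,
    )


def standard_score(
    hpc: SignalTrace,
    speed: SignalTrace,
    p: ScoringParams | None = None,
) -> StandardScoring:
    """Classic independent freezing and sleep scoring (the baseline).

    Freezing: immobility bouts ≥ 1.5 s with movements < 0.2 s ignored.
    Sleep: immobility bouts ≥ 60 s with movements < 1 s ignored, then
    theta/delta ratio bins inside sleep are split into two k-means groups:
    high-ratio bins become REM, the rest of sleep is SWS.  Freezing and
    sleep are detected independently, so on sessions containing freezing
    the two labels overlap — the overlap is reported in the diagnostics,
    not resolved.
    """
    p = p or ScoringParams()
    _check_alignment([hpc, speed])
    speed_thr = (
        p.speed_threshold
        if p.speed_threshold is not None
        else estimate_speed_threshold(speed)
    )
    mask = speed.samples < speed_thr
    if not mask.any():
        empty = IntervalSet()
        return StandardScoring(empty, empty, empty, empty, {"speed_threshold": speed_thr})
    raw = IntervalSet.from_mask(mask, speed.rate)
    freezing = raw.close_gaps(p.standard_freezing_max_gap).drop_short(
        p.standard_freezing_min_duration
    )
    sleep = raw.close_gaps(p.standard_sleep_max_gap).drop_short(
        p.standard_sleep_min_duration
    )
    diagnostics: dict = {
        "speed_threshold": speed_thr,
        "freezing_total_s": freezing.total_duration,
        "sleep_total_s": sleep.total_duration,
        "freezing_sleep_overlap_s": freezing.intersect(sleep).total_duration,
    }
    if sleep.is_empty():
        return StandardScoring(freezing, IntervalSet(), IntervalSet(), sleep, diagnostics)
    ratio = band_power_ratio(hpc, p.theta_band, p.delta_band, p.ratio_bin)
    mask_bins = sleep.rasterize(ratio.rate, len(ratio.samples))
    finite = np.isfinite(ratio.samples) & mask_bins
    try:
        thr = kmeans2_threshold(ratio.samples[finite]).threshold
    except (DegenerateDistributionError, InvalidParameterError):
        thr = np.inf  # cannot split: all sleep scored SWS
    rem = (
        IntervalSet.from_mask(
            np.isfinite(ratio.samples) & (ratio.samples > thr), ratio.rate
        ).intersect(sleep)
        if np.isfinite(thr)
        else IntervalSet()
    )
    sws = sleep.subtract(rem)
    diagnostics["theta_delta_threshold"] = None if not np.isfinite(thr) else float(thr)
    return StandardScoring(freezing, sws, rem, sleep, diagnostics)


# ---------------------------------------------------------------------------
# evaluation helper
# ---------------------------------------------------------------------------


def bin_labels(
    sets: dict[str, IntervalSet],
    total_duration: float,
    bin_duration: float = 1.0,
    fill: str = "",
) -> np.ndarray:
    """Per-bin state labels for agreement computations.

    Bin ``i`` covers ``[i·bin, (i+1)·bin)`` and takes the label of the set
    covering the majority of the bin (ties broken by ``sets`` order);
    uncovered bins get ``fill``.
    """
    n_bins = int(np.floor(total_duration / bin_duration))
    labels = np.full(n_bins, fill, dtype=object)
    coverage = np.zeros(n_bins)
    edges = np.arange(n_bins + 1) * bin_duration
    for label, ivs in sets.items():
        cov = np.zeros(n_bins)
        for iv in ivs:
            lo = max(0, int(np.floor(iv.start / bin_duration)))
            hi = min(n_bins, int(np.ceil(iv.end / bin_duration)))
            for b in range(lo, hi):
                cov[b] += max(
                    0.0, min(iv.end, edges[b + 1]) - max(iv.start, edges[b])
                )
        better = cov > coverage
        labels[better] = label
        coverage = np.maximum(coverage, cov)
    return labels
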