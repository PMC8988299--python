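# Methods

This note documents the scoring model, its parameters, the synthetic
benchmark, and the numerical and design choices made where the published
procedure leaves room.

## Scoring model

A session is scored from up to three time-aligned traces: one
neocortical LFP channel (nominally 1250 Hz), optionally one hippocampal
LFP channel, and a motion readout (angular speed, nominally 300 Hz).
Five detectors run in a fixed order — immobility → SWS → REM → quiet
wakefulness → freezing — and each operates on the remainder left by its
predecessors. This precedence is what guarantees a zero-overlap
partition; it also means a relabeling by an earlier detector can never
be "stolen back" by a later one.

All epochs are half-open intervals `[start, end)` in seconds. Touching
intervals merge; gap comparisons are strict (a gap is closed when it is
`< max_gap`) while duration filters are inclusive (a bout of exactly the
minimum survives). The published descriptions mix "more than" and
"longer than"; one convention is fixed here and used everywhere.

### Immobility

Speed below a threshold, gaps < 0.2 s closed, bouts ≥ 1.5 s kept. The
threshold is user-supplied or, by default, estimated as the two-cluster
k-means split of log speed. The estimate assumes the session contains
both movement and stillness; for sessions known to be all-active or
all-immobile, pass an explicit threshold.

### Slow-wave sleep

Cortical LFP → 9–17 Hz band-pass (4th-order Butterworth, forward-
backward, so zero phase) → Hilbert envelope → Gaussian smoothing with a
14 s window. "Window" is read as total support with SD = width/6; the
alternative reading (SD = 14 s) is available via configuration.
Smoothing joins individual spindle events into a plateau, so across
immobility the smoothed envelope is bimodal: a high SWS mode and a low
mode for everything else.

The threshold is the deterministic two-cluster k-means split of the
smoothed-envelope samples during immobility, subsampled to one value per
0.5 s to decorrelate. In one dimension the 2-means optimum is a
contiguous split of the sorted values, so it is solved exactly by a
prefix-sum scan over all splits rather than by Lloyd iterations — same
optimum, bit-reproducible, no initialization sensitivity. Thresholding
is restricted to immobility because the bimodality claim holds there;
scope is configurable.

Supra-threshold immobility is closed over gaps < 1 s (brief movements
within sleep), filtered to bouts ≥ 30 s, then re-intersected with
immobility so that the movement time bridged by gap closing is not
itself labeled sleep.

**Sleep-free sessions.** On a session without sleep the smoothed
envelope is unimodal, and a 2-means split of a unimodal sample is not
meaningless-looking: for a Gaussian it yields m = 2/π ≈ 0.64 (law of
total variance for a mean split). The effectiveness floor that declares
"no SWS" must therefore sit *above* that value; measured sweeps give
m ≈ 0.63–0.65 on unimodal synthetic sessions and m ≥ 0.85 on genuinely
bimodal ones, so the default floor is 0.75. Below it the scorer returns
an empty SWS set with a warning instead of thresholding noise.

### REM

Theta (6–9 Hz) / delta (0.5–4 Hz) power ratio in 1 s bins, computed as
mean squared band envelope per bin (the estimator and bin size are not
prescribed anywhere; 1 s matches the time scale of the decision).
Hippocampal mode compares the raw ratio against the fixed threshold 1;
cortical mode smooths the ratio (8 s Gaussian) and uses an Otsu
threshold, because cortical theta/delta runs lower than hippocampal.
Candidate epochs are maximal supra-threshold runs within
immobility-minus-SWS, at least 5 s long (a minimum is needed to avoid
single-bin flicker; none is published). A candidate is REM only if it
overlaps or starts within 30 s after an SWS epoch. By default REM may
not chain off other REM epochs; a `rem_chain` flag enables transitive
anchoring. With no SWS in the session, REM is empty by construction.

### Quiet wakefulness and freezing

Quiet wakefulness: epochs of the remaining immobility whose end lies
within 120 s before an SWS start (inclusive; overlap counts as zero
lead). Anchoring uses SWS starts only. Freezing is all immobility still
unlabeled, with gaps < 0.2 s closed and bouts ≥ 2 s kept; the 2 s
minimum is applied after quiet wakefulness has been subtracted. Closed
gaps are movements and become part of the freezing bout — with default
parameters immobility detection has already closed the same gaps, so
freezing stays inside detected immobility.

### The baseline scorer

`standard_score` reproduces the classic independent pipelines: freezing
as immobility ≥ 1.5 s (movements < 0.2 s ignored), sleep as immobility
≥ 60 s (movements < 1 s ignored) split into SWS/REM by a k-means
threshold on theta/delta ratio bins. Freezing and sleep are detected
independently and their overlap is reported, not resolved — the point of
the baseline is to exhibit this failure on data containing freezing.

## Parameters

| parameter | default | unit | role |
|---|---|---|---|
| `speed_threshold` | auto (k-means of log speed) | speed units | immobility boundary |
| `immobility_min_duration` / `immobility_max_gap` | 1.5 / 0.2 | s | immobility bout filter |
| `spindle_band` | 9–17 | Hz | sleep marker band |
| `theta_band` / `delta_band` | 6–9 / 0.5–4 | Hz | REM ratio bands |
| `spindle_smooth_window` | 14 | s | envelope smoothing (support) |
| `sws_min_duration` / `sws_max_gap` | 30 / 1 | s | SWS bout filter |
| `sws_effectiveness_floor` | 0.75 | – | declare session sleep-free below this m |
| `rem_ratio_threshold` | 1 | – | hippocampal-mode threshold |
| `cortical_ratio_smooth_window` | 8 | s | cortical-mode ratio smoothing |
| `rem_max_delay_after_sws` | 30 | s | REM anchoring window |
| `rem_min_duration` | 5 | s | REM candidate minimum |
| `quiet_wake_max_lead` | 120 | s | pre-sleep window |
| `freezing_min_duration` / `freezing_max_gap` | 2 / 0.2 | s | freezing bout filter |

The introduction-level literature sometimes quotes narrower exploratory
bands (theta 7–8.5 Hz, delta 1–4 Hz); the definitions above are the
operational ones and are used as defaults.

## Synthetic benchmark

The generator emulates exactly the statistical structure the classifier
assumes, no more:

* per-state narrowband oscillations — SWS: 1.5 Hz delta plus 12 Hz
  spindle bursts (0.7 s Hann-windowed, amplitude 0.8, 0.25 bursts/s);
  freezing: 4 Hz, amplitude 1.0, no spindles; REM: 7.5 Hz theta,
  amplitude 1.0; quiet wakefulness: mixed delta-dominated activity —on
  white noise of SD 0.2;
* narrowband components are OU-frequency-modulated sinusoids. A
  Wiener-phase-noise realization was rejected because its Lorentzian
  tails leak measurable 4 Hz power into the spindle band, which real
  respiration-coupled rhythms do not;
* spindle bursts are placed by a gamma renewal process (mean interval
  1/rate, shape 16, CV 0.25). Spindle recurrence in SWS is
  quasi-periodic; a memoryless process at the same rate produces
  minute-scale fluctuations of smoothed spindle power that real spindle
  trains do not show, and which would contradict the near-constant
  plateau the classifier rests on;
* motion traces: immobile states emit sub-threshold noise with
  occasional 0.1–0.18 s movement spikes (exercising gap closing), the
  active state clearly supra-threshold speed;
* session plans separate distinct immobile behaviors with brief active
  bouts, and place a 2–3 min exploration/settling bout between freezing
  and subsequent sleep. The latter reflects the behavioral premise of
  the quiet-wakefulness rule — animals do not fall asleep out of the
  freezing posture; without it, freezing that ends minutes before sleep
  onset is (by definition) labeled quiet wakefulness and the planned
  labels stop being a usable ground truth.

Deliberately absent: 1/f broadband structure, ripples, respiration-LFP
coupling, gradual state transitions, inter-animal variability. Passing
recovery tests on this benchmark therefore shows the pipeline implements
its stated decision rules correctly and robustly at realistic SNR; it
does not certify performance on real recordings, where mode separation
is set by physiology, not by a generator.

## Numerical choices

* Filters: Butterworth order 4 per pass, `sosfiltfilt`, with explicit
  mirror padding of three low-edge periods; the Hilbert transform is
  computed at the next fast FFT length; Gaussian smoothing uses FFT
  convolution (kernels reach ~17 500 taps at 1250 Hz) with reflect
  padding; unit-sum kernels make constants exact fixed points to ~1e-15.
* Otsu: candidate thresholds are interior histogram bin edges (256 bins
  by default). With well-separated modes, every edge across the empty
  gap ties; the middle maximizer is taken (the convention of reference
  implementations), with a 1e-12 relative tolerance for plateau
  detection.
* Degenerate distributions (relative spread ≤ 1e-9) raise a dedicated
  error; detectors catch it and degrade to empty results with warnings.
* Binned ratios with zero denominator power report `+inf` and warn.
* `bin_labels` resolves partially covered 1 s bins by majority coverage.
* Downsampling uses polyphase resampling with a Kaiser-windowed FIR
  anti-alias filter; any rational rate ratio is accepted.

## Known limitations

* Pre-sleep freezing is indistinguishable from quiet wakefulness by
  construction: any immobility ending < 2 min before SWS onset is
  labeled quiet wakefulness.
* The automatic speed threshold requires both moving and still time in
  the session.
* The cortical REM mode needs enough non-REM immobility in the session
  for the Otsu split of the ratio distribution to be meaningful.
* The wavelet spectrogram is for visualization only; no detector
  consumes it.
* Scoring is offline and session-level (thresholds are fit per
  session); there is no streaming mode, spindle-event detection, or
  micro-arousal scoring.
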