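# spindlescore

Automated behavioral-state scoring for freely-moving rodent
electrophysiology, built to solve one specific problem: **telling sleep
apart from freezing**.

## The problem

The standard way to score sleep in rodents is to detect immobility from a
motion readout and then split it into slow-wave sleep (SWS) and REM using
the theta/delta power ratio of the LFP. This works in plain rest
recordings, but it assumes *all* immobility is rest. In fear-conditioning
protocols animals also freeze — an immobile, fear-driven state
accompanied by a respiration-coupled ~4 Hz cortical rhythm. That rhythm
sits inside the delta band (0.5–4 Hz), so to a theta/delta scorer a long
freezing bout is indistinguishable from SWS, and the standard pipeline
labels the same epochs both "freezing" and "sleep".

## The method

Sleep spindles (9–17 Hz thalamocortical bursts) occur in SWS and not in
freezing, and the spindle band does not overlap the 4 Hz rhythm. The
scorer therefore uses **smoothed spindle-band power** as the sleep
marker:

1. **Immobility** — threshold the angular-speed trace; ignore movements
   < 0.2 s; keep bouts ≥ 1.5 s.
2. **SWS** — band-pass the cortical LFP at 9–17 Hz, take the Hilbert
   envelope `|H(x)|`, smooth with a 14 s Gaussian window. Across
   immobility this signal is bimodal (spindle events are frequent enough
   in SWS that smoothing joins them into a plateau); a deterministic
   two-cluster k-means threshold separates the modes. Supra-threshold
   immobility with movements < 1 s ignored and bouts ≥ 30 s is SWS. If
   the split is ineffective (`m = 1 − σᵢ/σ_tot < 0.75`) the session is
   declared sleep-free rather than thresholding noise.
3. **REM** — within the remaining immobility, bins where the hippocampal
   theta/delta ratio (6–9 Hz vs 0.5–4 Hz) exceeds 1, provided the epoch
   starts within 30 s of an SWS period (REM is nested in sleep cycles).
   Without a hippocampal channel, the cortical ratio is smoothed (8 s)
   and thresholded with the Otsu method instead.
4. **Quiet wakefulness** — remaining immobility ending < 2 min before an
   SWS onset (animals settle before falling asleep).
5. **Freezing** — everything still left, with interruptions < 0.2 s
   ignored and bouts ≥ 2 s kept.

Because every stage consumes the remainder of the previous ones, the four
states are **pairwise disjoint by construction** — the property the
compounded standard scorers lack.

No public recordings accompany the method, so the package ships a seeded
synthetic-session generator (state-dependent oscillations, spindle burst
trains, motion traces with brief movement artifacts) that provides ground
truth for every test.

## Worked example

```python
from spindlescore import score_session, standard_score
from spindlescore.synthetic import default_plan, generate_session

session = generate_session(default_plan(seed=7))   # ~35 min, all states
scoring = score_session(session.cortical, session.hpc, session.speed)
for name, epochs in scoring.states().items():
    print(f"{name:11s} {epochs.total_duration:7.1f} s in {len(epochs):2d} bouts")
print(f"spindle split m = {scoring.diagnostics['sws_effectiveness_m']:.3f}")
```

prints

```
sws           869.9 s in  5 bouts
rem           158.6 s in  3 bouts
quiet_wake    140.0 s in  4 bouts
freezing      450.0 s in  4 bouts
spindle split m = 0.910
```

against planned durations of 900 s SWS, 165 s REM, 105 s quiet
wakefulness and 450 s freezing: boundaries land within a few seconds of
the plan (quiet wakefulness absorbs the short immobile fringe right
before sleep onset), and the effectiveness `m` of 0.91 says the smoothed
spindle power was cleanly bimodal. On the same session the
baseline `standard_score` labels **all** immobility as sleep, including
every freezing bout — the failure the method exists to fix.

The same run is available from the shell:

```bash
spindlescore --synthetic default --seed 7 --out scored/ --standard
```

which writes `states.tsv` (columns `start_s  end_s  label`), a
`diagnostics.txt` side-car with thresholds and `m`, and a log. Real
recordings are scored by pointing the CLI at a Neuroscope-style
flat-binary file and a motion CSV:

```bash
spindlescore --lfp session.lfp --n-channels 32 --rate 1250 \
    --cortical-ch 4 --hpc-ch 17 --motion imu.csv --out scored/
```

Every scoring parameter is exposed as a flag (`--sws-min-duration`,
`--quiet-wake-max-lead`, …) or through `--config params.yaml`.

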