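"""The state-scoring pipelines: detectors, full scorer, baseline scorer."""

import numpy as np
import pytest

from spindlescore import (
    AlignmentError,
    IntervalSet,
    ScoringParams,
    SignalTrace,
    detect_freezing,
    detect_immobility,
    detect_quiet_wake,
    detect_rem,
    detect_sws,
    score_session,
    standard_score,
)
from spindlescore.scoring import bin_labels
from spindlescore.synthetic import StatePlan, generate_session, random_plan

P = ScoringParams()


def ivs(*pairs):
    return IntervalSet(pairs)


def truth_label_array(sess):
    keys = ("sws", "rem", "quiet_wake", "freezing")
    return bin_labels(
        {k: sess.truth[k] for k in keys}, sess.plan.total_duration, 1.0
    )


def agreement(sess, scoring):
    tl = truth_label_array(sess)
    dl = bin_labels(scoring.states(), sess.plan.total_duration, 1.0)
    imm = tl != ""
    return float((tl[imm] == dl[imm]).mean())


# ---------------------------------------------------------------------------
# immobility
# ---------------------------------------------------------------------------


class TestDetectImmobility:
    def test_still_trace_yields_single_spanning_interval(self):
        speed = SignalTrace(np.zeros(3000), 300.0)
        out = detect_immobility(speed, ScoringParams(speed_threshold=1.0))
        assert [(iv.start, iv.end) for iv in out] == [(0.0, 10.0)]

    def test_square_wave_speed(self):
        # 10 s still / 10 s moving alternation, 100 s trace
        rate = 300.0
        block = int(10 * rate)
        samples = np.tile(
            np.concatenate([np.zeros(block), np.full(block, 10.0)]), 5
        )
        out = detect_immobility(
            SignalTrace(samples, rate), ScoringParams(speed_threshold=5.0)
        )
        assert len(out) == 5
        assert np.allclose(out.durations, 10.0)

    def test_brief_speed_spike_ignored(self):
        rate = 300.0
        samples = np.zeros(int(60 * rate))
        spike = slice(int(30 * rate), int(30.1 * rate))
        samples[spike] = 10.0
        out = detect_immobility(
            SignalTrace(samples, rate), ScoringParams(speed_threshold=1.0)
        )
        assert len(out) == 1

    def test_raising_threshold_never_decreases_immobility(self, rng):
        speed = SignalTrace(np.abs(rng.normal(1.0, 1.0, 30000)), 300.0)
        durations = [
            detect_immobility(
                speed, ScoringParams(speed_threshold=thr)
            ).total_duration
            for thr in (0.3, 0.6, 1.0, 2.0, 4.0)
        ]
        assert all(b >= a for a, b in zip(durations, durations[1:]))


# ---------------------------------------------------------------------------
# SWS
# ---------------------------------------------------------------------------


class TestDetectSws:
    def test_detects_sws_half_not_freezing_half(self):
        plan = StatePlan(
            (("freezing", 300.0), ("sws", 300.0)), seed=3, physiological=False
        )
        sess = generate_session(plan)
        immobility = ivs((0, 600))
        sws, thr = detect_sws(sess.cortical, immobility, P)
        second_half = sws.intersect(ivs((300, 600))).total_duration
        first_half = sws.intersect(ivs((0, 300))).total_duration
        assert second_half >= 0.90 * 300
        assert first_half <= 0.05 * 300
        assert thr.effectiveness > 0.75

    def test_spindle_free_noise_yields_empty_with_warning(self, rng):
        lfp = SignalTrace(rng.normal(0, 0.2, int(400 * 1250)), 1250.0)
        with pytest.warns(UserWarning, match="no SWS detected"):
            sws, _ = detect_sws(lfp, ivs((0, 400)), P)
        assert sws.is_empty()

    def test_short_supra_threshold_bout_removed(self):
        # 25 s of sleep falls below the 30 s minimum; halving the minimum
        # recovers it
        plan = StatePlan(
            (("freezing", 200.0), ("sws", 25.0), ("freezing", 200.0)),
            seed=6,
            physiological=False,
        )
        sess = generate_session(plan)
        immobility = ivs((0, 425))
        loose = ScoringParams(sws_effectiveness_floor=0.0)
        sws, _ = detect_sws(sess.cortical, immobility, loose)
        assert sws.is_empty()
        short_ok = ScoringParams(
            sws_effectiveness_floor=0.0, sws_min_duration=15.0
        )
        sws2, _ = detect_sws(sess.cortical, immobility, short_ok)
        assert not sws2.is_empty()
        assert sws2.intersect(ivs((200, 225))).total_duration > 10


# ---------------------------------------------------------------------------
# REM
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def sleep_session():
    plan = StatePlan(
        (
            ("quiet_wake", 60.0),
            ("sws", 150.0),
            ("rem", 50.0),
            ("active", 10.0),
        ),
        seed=9,
    )
    return generate_session(plan)


class TestDetectRem:
    def test_theta_epoch_after_sws_is_rem(self, sleep_session):
        sess = sleep_session
        immobility = ivs((0, 260))
        sws = ivs((60, 210))
        rem = detect_rem(sess.hpc, immobility, sws, P, "hpc")
        assert rem.intersect(ivs((210, 260))).total_duration > 0.8 * 50

    def test_no_sws_means_no_rem(self, sleep_session):
        rem = detect_rem(
            sleep_session.hpc, ivs((0, 260)), IntervalSet(), P, "hpc"
        )
        assert rem.is_empty()

    def test_delta_dominated_epoch_not_rem(self, sleep_session):
        # the quiet-wake epoch (delta-dominated) precedes SWS; even though
        # REM detection scans all non-SWS immobility it must not fire there
        sess = sleep_session
        rem = detect_rem(sess.hpc, ivs((0, 260)), ivs((60, 210)), P, "hpc")
        assert rem.intersect(ivs((0, 60))).total_duration == 0.0

    def test_cortical_mode_agrees_with_hpc_mode(self, sleep_session):
        sess = sleep_session
        immobility = ivs((0, 260))
        sws = ivs((60, 210))
        rem_h = detect_rem(sess.hpc, immobility, sws, P, "hpc")
        rem_c = detect_rem(sess.cortical, immobility, sws, P, "cortical")
        n = 260
        mh = rem_h.rasterize(1.0, n)
        mc = rem_c.rasterize(1.0, n)
        union = (mh | mc).sum()
        assert union > 0
        assert (mh & mc).sum() / union >= 0.85


# ---------------------------------------------------------------------------
# quiet wakefulness and freezing (pure interval logic)
# ---------------------------------------------------------------------------


class TestDetectQuietWake:
    def test_epoch_shortly_before_sws_is_quiet_wake(self):
        immobility = ivs((0, 100), (150, 400))
        sws = ivs((200, 400))
        qw = detect_quiet_wake(immobility, sws, IntervalSet(), P)
        # [150,200) ends at SWS onset; [0,100) ends 100 s before it (< 2 min)
        assert [(iv.start, iv.end) for iv in qw] == [(0, 100), (150, 200)]

    def test_epoch_long_before_sws_is_not_quiet_wake(self):
        qw = detect_quiet_wake(ivs((0, 50), (300, 500)), ivs((300, 500)),
                               IntervalSet(), P)
        assert qw.is_empty()  # ends 250 s before onset

    def test_no_sws_no_quiet_wake(self):
        qw = detect_quiet_wake(ivs((0, 100)), IntervalSet(), IntervalSet(), P)
        assert qw.is_empty()


class TestDetectFreezing:
    def test_remainder_becomes_freezing(self):
        frz = detect_freezing(
            ivs((0, 100)), IntervalSet(), IntervalSet(), IntervalSet(), P
        )
        assert [(iv.start, iv.end) for iv in frz] == [(0, 100)]

    def test_short_fragment_dropped(self):
        frz = detect_freezing(
            ivs((0, 100)), ivs((1.5, 100)), IntervalSet(), IntervalSet(), P
        )
        assert frz.is_empty()

    def test_nearby_bouts_merged(self):
        frz = detect_freezing(
            ivs((0, 5), (5.1, 9)), IntervalSet(), IntervalSet(), IntervalSet(), P
        )
        assert [(iv.start, iv.end) for iv in frz] == [(0, 9)]


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


class TestScoreSession:
    def test_recovers_planned_timeline(self, mixed_session, mixed_scoring):
        assert agreement(mixed_session, mixed_scoring) >= 0.90

    def test_states_pairwise_disjoint_and_inside_immobility(self, mixed_scoring):
        states = list(mixed_scoring.states().values())
        for i in range(len(states)):
            for j in range(i + 1, len(states)):
                assert states[i].intersect(states[j]).total_duration == 0.0
        for s in states:
            inside = s.intersect(mixed_scoring.immobility).total_duration
            assert inside == pytest.approx(s.total_duration, abs=1e-6)

    def test_all_moving_session_scores_nothing(self):
        sess = generate_session(StatePlan((("active", 120.0),), seed=4))
        sc = score_session(
            sess.cortical, sess.hpc, sess.speed,
            ScoringParams(speed_threshold=0.5),
        )
        assert all(s.is_empty() for s in sc.states().values())

    def test_sleep_only_session_has_no_freezing(self):
        sess = generate_session(random_plan(21, state_mix="sleep"))
        sc = score_session(sess.cortical, sess.hpc, sess.speed)
        assert sc.freezing.total_duration <= 5.0
        covered = (
            sc.sws.total_duration
            + sc.rem.total_duration
            + sc.quiet_wake.total_duration
        )
        assert covered >= 0.9 * sess.immobility_truth.total_duration

    def test_deterministic(self, mixed_session, mixed_scoring):
        again = score_session(
            mixed_session.cortical,
            mixed_session.hpc,
            mixed_session.speed,
            ScoringParams(),
        )
        for name, s in mixed_scoring.states().items():
            assert again.states()[name] == s

    def test_misaligned_traces_rejected(self, mixed_session):
        short_speed = SignalTrace(
            mixed_session.speed.samples[: len(mixed_session.speed) // 2], 300.0
        )
        with pytest.raises(AlignmentError):
            score_session(
                mixed_session.cortical, mixed_session.hpc, short_speed
            )

    def test_diagnostics_reports_thresholds(self, mixed_scoring):
        d = mixed_scoring.diagnostics
        assert d["rem_mode"] == "hpc"
        assert d["sws_effectiveness_m"] > 0.75
        assert d["speed_threshold"] > 0


class TestStandardScore:
    def test_freezing_session_double_labeled_by_baseline_only(self):
        sess = generate_session(random_plan(31, state_mix="freezing"))
        with pytest.warns(UserWarning, match="no SWS detected"):
            proposed = score_session(sess.cortical, sess.hpc, sess.speed)
        baseline = standard_score(sess.hpc, sess.speed)
        frz = sess.truth["freezing"]
        overlap = baseline.freezing.intersect(baseline.sleep).total_duration
        assert overlap > 0.5 * frz.total_duration
        assert proposed.sws.intersect(frz).total_duration < 0.05 * frz.total_duration

    def test_sleep_session_baseline_and_proposed_sws_agree(self):
        sess = generate_session(random_plan(32, state_mix="sleep"))
        proposed = score_session(sess.cortical, sess.hpc, sess.speed)
        baseline = standard_score(sess.hpc, sess.speed)
        sleep_time = sess.truth["sws"].total_duration
        shared = baseline.sws.intersect(proposed.sws).total_duration
        assert shared >= 0.8 * min(sleep_time, proposed.sws.total_duration)

    def test_short_immobility_excluded_from_standard_freezing(self):
        rate = 300.0
        samples = np.full(int(30 * rate), 10.0)
        samples[int(10 * rate): int(11.4 * rate)] = 0.0  # 1.4 s still
        hpc = SignalTrace(np.random.default_rng(0).normal(0, 0.2, int(30 * 1250)),
                          1250.0)
        out = standard_score(
            hpc, SignalTrace(samples, rate), ScoringParams(speed_threshold=1.0)
        )
        assert out.freezing.is_empty()
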