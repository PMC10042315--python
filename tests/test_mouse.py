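"""Mouse session parsing, per-trial metrics and the 33 session features."""

import numpy as np
import pytest

from kinemetrics.cohort import SubjectSpec, generate_mouse_session
from kinemetrics.mouse import (
    MOUSE_FEATURE_NAMES,
    MouseSession,
    MouseTrial,
    median_session_features,
    parse_session,
    session_features,
    trial_metrics,
    write_session,
)

RATE = 60.0


def _straight_trial(
    start=(100.0, 100.0),
    target=(700.0, 100.0),
    radius=30.0,
    speed=600.0,
    pause_at=None,
    pause_dur=0.0,
):
    """Constant-speed straight path to the target centre, instant click."""
    start = np.asarray(start, dtype=float)
    target = np.asarray(target, dtype=float)
    dist = np.linalg.norm(target - start)
    u = (target - start) / dist
    dt = 1.0 / RATE
    n = int(np.ceil(dist / speed / dt)) + 1
    pos = [start + u * min(speed * i * dt, dist) for i in range(n)]
    if pause_at is not None:
        i_p = int(pause_at * n)
        hold = [pos[i_p]] * int(round(pause_dur / dt))
        pos = pos[:i_p] + hold + pos[i_p:]
    t = np.arange(len(pos)) * dt
    samples = np.column_stack([t, np.asarray(pos)])
    down_t = t[-1] + dt
    buttons = [
        {"type": "down", "t": down_t, "x": float(target[0]), "y": float(target[1])},
        {"type": "up", "t": down_t + 0.08, "x": float(target[0]), "y": float(target[1])},
    ]
    return MouseTrial(
        target_center=target, target_radius=radius, cue_t=0.0,
        samples=samples, buttons=buttons, cued=True,
    )


@pytest.fixture(scope="module")
def session():
    spec = SubjectSpec("m", 0.5, "ataxic", 77, days=6)
    return generate_mouse_session(spec)


class TestParseSession:
    def test_roundtrip_is_bit_identical(self, session, tmp_path):
        path = tmp_path / "s.json"
        write_session(session, path)
        back = parse_session(path)
        assert back.session_id == session.session_id
        for r0, r1 in zip(session.rounds, back.rounds):
            for t0, t1 in zip(r0, r1):
                assert np.array_equal(t0.samples, t1.samples)
                assert t0.buttons == t1.buttons

    def test_8x9_session_keeps_64_cued_trials(self, session):
        assert sum(len(r) for r in session.rounds) == 72
        assert len(session.cued_trials()) == 64
        assert all(not r[0].cued for r in session.rounds)

    def test_duplicated_timestamp_rejected(self, session, tmp_path):
        import json

        path = tmp_path / "bad.json"
        write_session(session, path)
        doc = json.loads(path.read_text())
        doc["rounds"][0]["trials"][1]["samples"][3][0] = doc["rounds"][0]["trials"][1][
            "samples"
        ][2][0]
        with pytest.raises(ValueError, match="strictly increasing"):
            parse_session(doc)

    def test_incomplete_trailing_trial_dropped(self, session, tmp_path):
        import json

        path = tmp_path / "trunc.json"
        write_session(session, path)
        doc = json.loads(path.read_text())
        doc["rounds"][-1]["trials"][-1]["buttons"] = []
        back = parse_session(doc)
        assert back.meta["n_dropped"] == 1
        assert len(back.cued_trials()) == 63


class TestTrialMetrics:
    def test_ideal_straight_trial(self):
        m = trial_metrics(_straight_trial())
        assert m.task_axis_crossings == 0
        assert m.movement_error == pytest.approx(0.0, abs=1e-9)
        assert m.movement_offset == pytest.approx(0.0, abs=1e-9)
        assert m.target_reentries == 0
        assert m.n_pauses == 0
        assert m.orthogonal_direction_changes == 0

    def test_timing_additivity_is_exact(self, session):
        for tr in session.cued_trials():
            m = trial_metrics(tr)
            if np.isfinite(m.execution_time_s):
                assert m.execution_time_s + m.verification_time_s == pytest.approx(
                    m.movement_time_s, abs=1e-12
                )

    def test_injected_stop_detected_as_one_pause(self):
        m = trial_metrics(_straight_trial(pause_at=0.5, pause_dur=0.2))
        assert m.n_pauses == 1
        assert m.longest_pause_s == pytest.approx(0.2, abs=1.5 / RATE)

    def test_two_segment_path_main_sm_fraction(self):
        # Two sequential minimum-jerk segments: 300 px then 100 px along x.
        from kinemetrics import minjerk

        dt = 1.0 / RATE
        t1 = np.arange(0, 1.0 + dt / 2, dt)
        x1 = 100.0 + 300.0 * (10 * t1**3 - 15 * t1**4 + 6 * t1**5)
        t2 = np.arange(dt, 0.8 + dt / 2, dt)
        tau = t2 / 0.8
        x2 = 400.0 + 100.0 * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
        x = np.concatenate([x1, x2])
        t = np.arange(len(x)) * dt
        samples = np.column_stack([t, x, np.full(len(x), 200.0)])
        down_t = t[-1] + dt
        trial = MouseTrial(
            target_center=np.array([500.0, 200.0]), target_radius=20.0,
            cue_t=0.0, samples=samples,
            buttons=[
                {"type": "down", "t": down_t, "x": 500.0, "y": 200.0},
                {"type": "up", "t": down_t + 0.05, "x": 500.0, "y": 200.0},
            ],
        )
        m = trial_metrics(trial)
        assert m.n_submovements == 2
        assert m.frac_dist_main_sm == pytest.approx(0.75, rel=0.02)
        # Execution ends at target entry (radius 20), so the path denominator
        # of the main-SM share is 380 px, not the full 400 px task distance.
        assert m.main_sm_share == pytest.approx(300.0 / 380.0, rel=0.03)

    def test_click_slip_and_duration(self):
        tr = _straight_trial()
        tr.buttons[1]["x"] += 3.0
        tr.buttons[1]["y"] += 4.0
        m = trial_metrics(tr)
        assert m.click_slip == pytest.approx(5.0)
        assert m.click_duration_s == pytest.approx(0.08)

    def test_no_target_entry_flags_timing_missing(self):
        tr = _straight_trial(target=(700.0, 100.0))
        tr.target_center = np.array([700.0, 500.0])  # cursor never enters
        m = trial_metrics(tr)
        assert np.isnan(m.execution_time_s)
        assert np.isfinite(m.movement_time_s)


class TestSessionFeatures:
    def test_exactly_33_canonical_features(self, session):
        f = session_features(session)
        assert list(f) == MOUSE_FEATURE_NAMES
        assert len(f) == 33

    def test_identical_trials_zero_cv_and_sd(self):
        trials = [_straight_trial() for _ in range(9)]
        trials[0].cued = False
        sess = MouseSession("t", (800, 600), rounds=[trials])
        f = session_features(sess)
        for name in MOUSE_FEATURE_NAMES:
            if name.endswith("_cv") or name.endswith("_sd"):
                assert f[name] == pytest.approx(0.0, abs=1e-12), name

    def test_two_trial_toy_population_cv(self):
        t1 = _straight_trial(speed=600.0)
        t2 = _straight_trial(speed=200.0)  # three times slower: MT 3x
        sess = MouseSession("toy", (800, 600), rounds=[[t1, t2]])
        f = session_features(sess, min_valid_trials=2)
        mt1 = trial_metrics(t1).movement_time_s
        mt2 = trial_metrics(t2).movement_time_s
        mean = (mt1 + mt2) / 2
        cv = (abs(mt2 - mt1) / 2) / mean  # population-SD convention
        assert f["movement_time"] == pytest.approx(mean)
        assert f["movement_time_cv"] == pytest.approx(cv, rel=1e-9)

    def test_too_few_valid_trials_rejected(self):
        sess = MouseSession("few", (800, 600), rounds=[[_straight_trial()]])
        with pytest.raises(ValueError, match="valid cued"):
            session_features(sess)

    def test_scale_equivariance(self, session):
        f1 = session_features(session)
        scaled = MouseSession(
            session_id="x2",
            screen=(session.screen[0] * 2, session.screen[1] * 2),
            rounds=[
                [
                    MouseTrial(
                        target_center=t.target_center * 2,
                        target_radius=t.target_radius * 2,
                        cue_t=t.cue_t,
                        samples=np.column_stack(
                            [t.samples[:, 0], t.samples[:, 1:] * 2]
                        ),
                        buttons=[
                            {**b, "x": b["x"] * 2, "y": b["y"] * 2}
                            for b in t.buttons
                        ],
                        cued=t.cued,
                    )
                    for t in rnd
                ]
                for rnd in session.rounds
            ],
            rate_hz=session.rate_hz,
        )
        f2 = session_features(scaled)
        px_features = [
            "max_speed", "max_accel", "max_axis_deviation", "movement_error",
            "movement_variability", "dist_to_target_end_main_sm", "click_slip",
        ]
        for name in px_features:
            assert f2[name] == pytest.approx(2.0 * f1[name], rel=0.02), name
        invariant = [
            "movement_time", "movement_time_cv", "n_pauses", "normalized_jerk",
            "target_reentries", "n_submovements", "frac_dist_main_sm",
            "main_sm_share", "task_axis_crossings", "noise_to_force_ratio",
        ]
        for name in invariant:
            assert f2[name] == pytest.approx(f1[name], rel=0.02), name


class TestMedianSplits:
    def _rows(self, n):
        return [
            {name: float(i) for name in MOUSE_FEATURE_NAMES} for i in range(n)
        ]

    def test_eight_sessions_split_4_4(self):
        rows = self._rows(8)
        a = median_session_features(rows, "first_half")
        b = median_session_features(rows, "second_half")
        assert a["movement_time"] == 1.5  # median of 0-3
        assert b["movement_time"] == 5.5  # median of 4-7

    def test_six_sessions_split_3_3(self):
        rows = self._rows(6)
        a = median_session_features(rows, "first_half")
        b = median_session_features(rows, "second_half")
        assert a["movement_time"] == 1.0
        assert b["movement_time"] == 4.0

    def test_identical_sessions_median_is_any(self):
        rows = [dict.fromkeys(MOUSE_FEATURE_NAMES, 2.5)] * 5
        assert median_session_features(rows)["n_pauses"] == 2.5


class TestGeneratorBookkeeping:
    def test_injected_pause_schedule_recorded(self):
        spec = SubjectSpec("p", 0.8, "ataxic", 5, days=6, within_subject_sd=0.0)
        sess, truth = generate_mouse_session(spec, return_truth=True)
        assert len(truth) > 0
        f = session_features(sess)
        assert f["n_pauses"] >= 1.0  # injected pauses are detectable

    def test_determinism(self):
        spec = SubjectSpec("d", 0.4, "ataxic", 31, days=6)
        s1 = generate_mouse_session(spec, session_index=2)
        s2 = generate_mouse_session(spec, session_index=2)
        for r0, r1 in zip(s1.rounds, s2.rounds):
            for t0, t1 in zip(r0, r1):
                assert np.array_equal(t0.samples, t1.samples)

    def test_invalid_round_geometry_rejected(self):
        spec = SubjectSpec("e", 0.2, "ataxic", 1, days=6)
        with pytest.raises(ValueError):
            generate_mouse_session(spec, rounds=0)
        with pytest.raises(ValueError):
            generate_mouse_session(spec, targets_per_round=1)
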