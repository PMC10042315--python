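"""Submovement decomposition, kinematics, shape basis and the 85-feature schema."""

import numpy as np
import pytest

from kinemetrics import minjerk
from kinemetrics.submovements import (
    FEATURE_NAMES,
    KEY_FEATURES,
    Submovement,
    analytic_shape_basis,
    assemble_feature_vector,
    feature_dictionary,
    fit_sm_shape_basis,
    movement_plane,
    reconstruct_velocity,
    score_submovements,
    segment_submovements,
    sm_kinematics,
    sm_pc_score_features,
)

RATE = 100.0


def _pulse_accel(distance, duration, rate=RATE):
    t = np.arange(int(round(duration * rate)) + 1) / rate
    return minjerk.acceleration(t, distance, duration)


def _pulse_velocity(distance, duration, rate=RATE):
    t = np.arange(int(round(duration * rate)) + 1) / rate
    return minjerk.velocity(t, distance, duration)


class TestReconstructVelocity:
    def test_zero_acceleration_gives_zero_velocity(self):
        v, _ = reconstruct_velocity(np.zeros((500, 3)), RATE)
        assert np.all(v == 0.0)

    def test_minjerk_pulse_peak_speed(self):
        a = np.zeros((400, 3))
        pulse = _pulse_accel(0.5, 1.0)
        a[100 : 100 + len(pulse), 0] = pulse
        v, _ = reconstruct_velocity(a, RATE)
        assert np.abs(v[:, 0]).max() == pytest.approx(0.9375, rel=0.02)

    def test_endpoints_exactly_zero(self, rng):
        v, _ = reconstruct_velocity(rng.normal(size=(300, 3)), RATE)
        assert np.all(v[0] == 0.0)
        assert np.allclose(v[-1], 0.0, atol=1e-12)


class TestMovementPlane:
    def test_single_axis_motion(self, rng):
        v = np.zeros((500, 3))
        v[:, 0] = rng.normal(size=500)
        bv = movement_plane(v, RATE)
        assert np.allclose(np.abs(bv.plane[0]), [1, 0, 0], atol=1e-9)
        assert bv.variance_explained[0] == pytest.approx(1.0)
        assert bv.variance_explained[1] == pytest.approx(0.0, abs=1e-12)

    def test_planar_4_to_1_variance_ratio(self, rng):
        t = np.linspace(0, 4 * np.pi, 2000)
        v = np.column_stack([2.0 * np.sin(t), np.sin(2 * t), np.zeros_like(t)])
        bv = movement_plane(v, RATE)
        ratio = bv.variance_explained[0] / bv.variance_explained[1]
        assert ratio == pytest.approx(4.0, rel=0.05)

    def test_out_of_plane_noise_barely_tilts_plane(self, rng):
        t = np.linspace(0, 4 * np.pi, 2000)
        clean = np.column_stack([2.0 * np.sin(t), np.sin(2 * t), np.zeros_like(t)])
        noisy = clean.copy()
        noisy[:, 2] += rng.normal(0, 0.1 * np.sqrt(2.0), size=len(t))  # 1% variance
        b0 = movement_plane(clean, RATE)
        b1 = movement_plane(noisy, RATE)
        for i in range(2):
            cos = abs(np.dot(b0.plane[i], b1.plane[i]))
            assert np.degrees(np.arccos(np.clip(cos, -1, 1))) < 5.0

    def test_rank_zero_bout_skipped(self):
        assert movement_plane(np.zeros((100, 3)), RATE) is None

    def test_plane_vectors_orthonormal(self, rng):
        bv = movement_plane(rng.normal(size=(400, 3)), RATE)
        g = bv.plane @ bv.plane.T
        assert np.allclose(g, np.eye(2), atol=1e-10)


class TestSegmentSubmovements:
    def test_single_positive_bell(self):
        v = np.concatenate([np.zeros(20), _pulse_velocity(0.3, 0.5), np.zeros(20)])
        sms = segment_submovements(v, RATE, "pc1")
        assert len(sms) == 1
        assert sms[0].duration_s == pytest.approx(0.5, abs=2 / RATE)

    def test_positive_then_negative_bell(self):
        v = np.concatenate(
            [_pulse_velocity(0.3, 0.5), -_pulse_velocity(0.2, 0.4)]
        )
        sms = segment_submovements(v, RATE, "pc2")
        assert len(sms) == 2
        assert all(sm.v_profile.max() > 0 for sm in sms)  # sign-flipped to positive
        assert all(sm.direction == "pc2" for sm in sms)

    def test_subthreshold_ripple_rejected(self, rng):
        v = 0.01 * np.sin(np.linspace(0, 20 * np.pi, 2000))
        assert segment_submovements(v, RATE, "pc1", min_peak=0.05) == []

    def test_too_short_segments_rejected(self):
        v = np.concatenate([np.zeros(5), _pulse_velocity(0.05, 0.05), np.zeros(5)])
        assert segment_submovements(v, RATE, "pc1", min_dur_s=0.08) == []

    def test_supports_disjoint_and_sign_consistent(self, rng):
        v = np.cumsum(rng.normal(size=3000)) / 50.0
        sms = segment_submovements(v, RATE, "pc1")
        # Each kept SM lies between genuine sign changes: profiles never cross 0.
        for sm in sms:
            assert sm.v_profile.min() >= 0.0
            assert sm.v_profile.max() >= 0.05


class TestSmKinematics:
    def _sm(self, distance, duration, rate=RATE):
        sm = Submovement(
            direction="pc1", v_profile=_pulse_velocity(distance, duration, rate),
            rate_hz=rate,
        )
        return sm_kinematics(sm)

    def test_minjerk_distance_and_peak_velocity(self):
        sm = self._sm(0.5, 1.0)
        assert sm.distance_m == pytest.approx(0.5, rel=0.01)
        assert sm.peak_velocity == pytest.approx(0.9375, rel=0.01)
        assert sm.peak_acceleration == pytest.approx(
            minjerk.peak_acceleration(0.5, 1.0), rel=0.03
        )

    def test_normalized_jerk_matches_analytic_oracle(self):
        # High-resolution oracle on the closed-form profile: for a minimum-jerk
        # pulse NJ^2 = 720 / (15/8)^2 regardless of (L, D).
        oracle = np.sqrt(720.0 / (15.0 / 8.0) ** 2)
        sm = self._sm(0.4, 1.2, rate=1000.0)
        assert sm.normalized_jerk == pytest.approx(oracle, rel=0.03)

    def test_normalized_jerk_time_rescale_invariant(self):
        a = self._sm(0.5, 0.6, rate=1000.0)
        b = self._sm(0.5, 1.2, rate=1000.0)  # D -> 2D, v -> v/2: same shape class
        assert a.normalized_jerk == pytest.approx(b.normalized_jerk, rel=0.01)

    def test_duration_groups(self):
        assert self._sm(0.02, 0.15).duration_group == "short"
        assert self._sm(0.2, 0.5).duration_group == "long"


class TestShapeBasis:
    def _long_pool(self, rng, n=80, noise=0.02):
        sms = []
        for _ in range(n):
            d = rng.uniform(0.25, 0.6)
            v = _pulse_velocity(rng.uniform(0.1, 0.3), d)
            v = v + rng.normal(0, noise * v.max(), size=len(v))
            sms.append(Submovement(direction="pc1", v_profile=v, rate_hz=RATE))
        return sms

    def test_component1_tracks_mean_curve(self, rng):
        basis = fit_sm_shape_basis(self._long_pool(rng))
        assert basis.source == "pca"
        r = np.corrcoef(basis.components[0], basis.mean_curve)[0, 1]
        assert abs(r) >= 0.9

    def test_identical_pool_component1_is_the_shape(self):
        v = _pulse_velocity(0.2, 0.5)
        sms = [
            Submovement(direction="pc1", v_profile=v.copy(), rate_hz=RATE)
            for _ in range(60)
        ]
        basis = fit_sm_shape_basis(sms)
        from kinemetrics.submovements import _resample_unit_peak

        shape = _resample_unit_peak(v, basis.resample_len)
        shape /= np.linalg.norm(shape)
        assert np.allclose(np.abs(basis.components[0]), np.abs(shape), atol=1e-8)

    def test_components_orthonormal(self, rng):
        basis = fit_sm_shape_basis(self._long_pool(rng))
        g = basis.components @ basis.components.T
        assert np.allclose(g, np.eye(5), atol=1e-8)

    def test_small_pool_falls_back_to_analytic(self):
        basis = fit_sm_shape_basis([], min_profiles=50)
        assert basis.source == "analytic"
        g = basis.components @ basis.components.T
        assert np.allclose(g, np.eye(5), atol=1e-8)
        # First function: single half-wave with its positive peak attainably early.
        assert basis.components[0].max() > 0

    def test_scores_reconstruct_low_rank_ensemble(self, rng):
        sms = self._long_pool(rng, n=120, noise=0.05)
        basis = fit_sm_shape_basis(sms)
        score_submovements(sms, basis)
        # 5 components capture nearly all variance of this low-rank ensemble.
        from kinemetrics.submovements import _resample_unit_peak

        errs = []
        for sm in sms:
            curve = _resample_unit_peak(sm.v_profile, basis.resample_len)
            recon = sm.pc_scores @ basis.components
            errs.append(np.linalg.norm(curve - recon) / np.linalg.norm(curve))
        assert np.median(errs) < 0.15


class TestPcScoreFeatures:
    def _sms_with_scores(self, scores, direction="pc1", duration=0.5):
        sms = []
        for s in scores:
            sm = Submovement(
                direction=direction,
                v_profile=_pulse_velocity(0.2, duration),
                rate_hz=RATE,
            )
            sm.pc_scores = np.asarray(s, dtype=float)
            sms.append(sm)
        return sms

    def test_equal_scores_zero_sd(self):
        sms = self._sms_with_scores([[1, 2, 3, 4, 5]] * 10)
        f = sm_pc_score_features(sms)
        assert f["sm_pc1_score_pc1_sd"] == 0.0
        assert f["sm_pc3_score_pc1_absmean"] == 3.0

    def test_gaussian_kurtosis_non_excess_convention(self, rng):
        scores = rng.normal(size=(10000, 5))
        f = sm_pc_score_features(self._sms_with_scores(scores))
        for k in range(1, 6):
            assert f[f"sm_pc{k}_score_pc1_kurtosis"] == pytest.approx(3.0, abs=0.2)

    def test_block_is_30_features_with_small_cells_missing(self):
        f = sm_pc_score_features(self._sms_with_scores([[1, 1, 1, 1, 1]] * 3))
        assert len(f) == 30
        assert np.isnan(f["sm_pc1_score_pc1_kurtosis"])  # n < 4
        assert np.isnan(f["sm_pc1_score_pc2_absmean"])  # empty cell


class TestFeatureSchema:
    def test_85_names_26_key(self):
        assert len(FEATURE_NAMES) == 85
        assert len(set(FEATURE_NAMES)) == 85
        assert len(KEY_FEATURES) == 26
        assert "ai_mean" in KEY_FEATURES and "ai_entropy" in KEY_FEATURES

    def test_each_sm_kinematic_contributes_8(self):
        for q in ("distance", "velocity", "acceleration", "jerk", "duration"):
            assert sum(n.startswith(f"sm_{q}_") for n in FEATURE_NAMES) == 8

    def test_each_pc_component_contributes_6(self):
        for k in range(1, 6):
            assert sum(n.startswith(f"sm_pc{k}_score_") for n in FEATURE_NAMES) == 6

    def test_assemble_with_missing_block_still_emits_85(self):
        vec = assemble_feature_vector(ai_features={"ai_mean": 0.5})
        s = vec.as_series()
        assert len(s) == 85
        assert s["ai_mean"] == 0.5
        assert np.isnan(s["total_power"])
        assert len(vec.key_values()) == 26

    def test_unknown_feature_rejected(self):
        with pytest.raises(KeyError):
            assemble_feature_vector(ai_features={"bogus": 1.0})

    def test_feature_dictionary_matches_schema(self):
        d = feature_dictionary()
        assert list(d["feature"]) == FEATURE_NAMES
        assert int(d["key"].sum()) == 26


class TestRecoveryFromConstructedBouts:
    """k non-overlapping pulses per direction are recovered exactly."""

    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_k_pulse_recovery(self, k, rng):
        from kinemetrics.submovements import extract_bout_submovements
        from kinemetrics.activity import ActivityBout

        rate = 100.0
        n = int(8.0 * rate)
        e1 = np.array([1.0, 0.0, 0.0])
        e2 = np.array([0.0, 1.0, 0.0])
        samples = np.zeros((n, 3))
        truth = {"pc1": [], "pc2": []}
        t0 = 0.3  # shared timeline: pulses of the two directions interleave
        for axis, e, scale in (("pc1", e1, 1.0), ("pc2", e2, 0.45)):
            for i in range(k):
                D = rng.uniform(0.3, 0.5)
                L = rng.uniform(0.1, 0.2) * scale
                sign = (-1.0) ** i
                t = np.arange(int(D * rate) + 1) / rate
                i0 = int(t0 * rate)
                samples[i0 : i0 + len(t)] += (
                    sign * minjerk.acceleration(t, L, D)[:, None] * e[None, :]
                )
                truth[axis].append(minjerk.peak_velocity(L, D))
                t0 += D + rng.uniform(0.3, 0.5)
        bout = ActivityBout(0, n, 0, 0, n / rate, np.empty(0))
        sms = extract_bout_submovements(bout, samples, rate)
        for axis in ("pc1", "pc2"):
            got = sorted(
                sm.peak_velocity for sm in sms if sm.direction == axis
            )
            assert len(got) == k
            for g, tv in zip(got, sorted(truth[axis])):
                assert g == pytest.approx(tv, rel=0.05)
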