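"""Per-subject wearable pipeline: raw recording -> 85-feature vectors.

Composes preprocessing (filtering, noise calibration, day segmentation) with
the activity and submovement extractors, caching per-period intermediates so
feature vectors for arbitrary period subsets (all days, days 1-3, days 4-6)
are cheap to assemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import activity as act
from . import submovements as smv
from .preprocess import (
    AccelRecording,
    DaySegmentation,
    bandpass,
    estimate_noise_variance,
    segment_days,
)

__all__ = ["ExtractionConfig", "PeriodData", "WearableExtractor"]


@dataclass
class ExtractionConfig:
    """All tunables of the wearable feature pipeline."""

    low_hz: float = 0.1
    high_hz: float = 20.0
    filter_order: int = 6
    ai_window_s: float = 1.0
    inactivity_threshold: float = act.DEFAULT_INACTIVITY_THRESHOLD
    bout_threshold: float = 0.1
    intensity_cuts: tuple[float, float] = act.DEFAULT_INTENSITY_CUTS
    bout_min_s: float = 4.0
    bout_max_s: float = 18.0
    sm_min_peak: float = smv.MIN_PEAK_VELOCITY
    sm_min_dur_s: float = smv.MIN_SM_DURATION_S
    min_night_h: float = 4.0
    max_night_h: float = 14.0
    smooth_h: float = 1.0
    max_periods: int = 6


@dataclass
class PeriodData:
    """Cached per-24h-period intermediates."""

    ai_values: np.ndarray            # daytime AI, one value per window
    dir_share: np.ndarray            # per-window PC1 variance share (%)
    bout_peak_acc: np.ndarray
    bout_mean_jerk: np.ndarray
    sms: list[smv.Submovement]
    band_power: float
    daytime_s: float
    n_bouts: int


class WearableExtractor:
    """Filter, segment and featurize one subject's recording once; then
    assemble feature vectors for any subset of 24-h periods."""

    def __init__(
        self,
        recording: AccelRecording,
        config: ExtractionConfig | None = None,
        night_override: list[tuple[float, float]] | None = None,
    ):
        self.config = cfg = config or ExtractionConfig()
        self.recording = recording
        self.filtered = bandpass(
            recording, cfg.low_hz, cfg.high_hz, cfg.filter_order
        )
        self.noise_var = estimate_noise_variance(self.filtered, cfg.ai_window_s)
        full_ai = act.activity_index(
            self.filtered,
            self.noise_var,
            window_s=cfg.ai_window_s,
            inactivity_threshold=cfg.inactivity_threshold,
        )
        self.segmentation: DaySegmentation = segment_days(
            recording,
            full_ai.values,
            ai_window_s=cfg.ai_window_s,
            min_night_h=cfg.min_night_h,
            max_night_h=cfg.max_night_h,
            smooth_h=cfg.smooth_h,
            max_periods=cfg.max_periods,
            override=night_override,
        )
        self.periods: list[PeriodData] = [
            self._extract_period(p) for p in range(self.segmentation.n_periods)
        ]

    def release_signals(self) -> None:
        """Drop the raw and filtered sample arrays (cohort runs hold many
        extractors; the cached per-period data suffice for feature assembly)."""
        self.recording.samples = np.empty((0, 3))
        self.filtered.samples = np.empty((0, 3))

    def _extract_period(self, period: int) -> PeriodData:
        cfg = self.config
        idx = self.segmentation.daytime_indices([period])
        ai = act.activity_index(
            self.filtered,
            self.noise_var,
            window_s=cfg.ai_window_s,
            inactivity_threshold=cfg.inactivity_threshold,
            sample_indices=idx,
        )
        dshare = self._window_shares(idx, ai)
        bouts = act.extract_bouts(
            ai,
            bout_threshold=cfg.bout_threshold,
            rate_hz=self.filtered.rate_hz,
            min_dur_s=cfg.bout_min_s,
            max_dur_s=cfg.bout_max_s,
        )
        day = self.filtered.samples[idx]
        rate = self.filtered.rate_hz
        dt = 1.0 / rate
        bk_acc, bk_jerk = [], []
        sms: list[smv.Submovement] = []
        for bout in bouts:
            seg = day[bout.start : bout.end]
            if seg.shape[0] >= 3:
                bk_acc.append(float(np.linalg.norm(seg, axis=1).max()))
                jerk = np.gradient(seg, dt, axis=0)
                bk_jerk.append(float(np.linalg.norm(jerk, axis=1).mean()))
            sms.extend(
                smv.extract_bout_submovements(
                    bout,
                    day,
                    rate,
                    min_peak=cfg.sm_min_peak,
                    min_dur_s=cfg.sm_min_dur_s,
                )
            )
        try:
            power = act.total_power(self.filtered, sample_indices=idx)
        except ValueError:
            power = np.nan
        return PeriodData(
            ai_values=ai.values,
            dir_share=dshare,
            bout_peak_acc=np.asarray(bk_acc),
            bout_mean_jerk=np.asarray(bk_jerk),
            sms=sms,
            band_power=power,
            daytime_s=len(idx) / self.filtered.rate_hz,
            n_bouts=len(bouts),
        )

    def _window_shares(self, idx: np.ndarray, ai: act.ActivityIndexSeries) -> np.ndarray:
        x = self.filtered.samples[idx]
        w = int(round(ai.window_s * self.filtered.rate_hz))
        n_win = min(x.shape[0] // w, ai.values.size)
        xw = x[: n_win * w].reshape(n_win, w, 3)
        xw = xw - xw.mean(axis=1, keepdims=True)
        cov = np.einsum("nti,ntj->nij", xw, xw) / w
        eig = np.linalg.eigvalsh(cov)
        total = eig.sum(axis=1)
        share = np.full(n_win, np.nan)
        ok = total > 0
        share[ok] = 100.0 * eig[ok, -1] / total[ok]
        return share

    def submovements(self, periods: list[int] | None = None) -> list[smv.Submovement]:
        sel = range(len(self.periods)) if periods is None else periods
        return [sm for p in sel for sm in self.periods[p].sms]

    def feature_vector(
        self,
        basis: smv.ShapeBasis,
        periods: list[int] | None = None,
        subject_id: str = "",
        period_label: str = "all",
    ) -> smv.WearableFeatureVector:
        """Assemble the 85-feature vector over the selected periods."""
        cfg = self.config
        sel = list(range(len(self.periods))) if periods is None else list(periods)
        pds = [self.periods[p] for p in sel]
        if not pds:
            raise ValueError("no periods selected")
        ai_vals = np.concatenate([p.ai_values for p in pds])
        ai = act.ActivityIndexSeries(
            values=ai_vals,
            window_s=cfg.ai_window_s,
            inactivity_threshold=cfg.inactivity_threshold,
        )
        ai_feats = act.ai_distribution_features(ai, intensity_cuts=cfg.intensity_cuts)

        share = np.concatenate([p.dir_share for p in pds])
        active = ~ai.inactivity_mask
        c1, c2 = cfg.intensity_cuts
        dir_feats = {}
        for name, mask in {
            "directionality_low_ai": active & (ai_vals < c1),
            "directionality_moderate_ai": active & (ai_vals >= c1) & (ai_vals < c2),
            "directionality_high_ai": active & (ai_vals >= c2),
        }.items():
            v = share[mask & np.isfinite(share)]
            dir_feats[name] = float(v.mean()) if v.size else np.nan

        weights = np.array([p.daytime_s for p in pds])
        powers = np.array([p.band_power for p in pds])
        okp = np.isfinite(powers)
        spectral = {
            "total_power": float(np.average(powers[okp], weights=weights[okp]))
            if okp.any()
            else np.nan
        }

        peak_acc = np.concatenate([p.bout_peak_acc for p in pds])
        mean_jerk = np.concatenate([p.bout_mean_jerk for p in pds])
        bout_feats = {
            "bout_acceleration_mean": float(peak_acc.mean()) if peak_acc.size else np.nan,
            "bout_acceleration_sd": float(peak_acc.std()) if peak_acc.size > 1 else np.nan,
            "bout_jerk_mean": float(mean_jerk.mean()) if mean_jerk.size else np.nan,
            "bout_jerk_sd": float(mean_jerk.std()) if mean_jerk.size > 1 else np.nan,
        }

        sms = [sm for p in pds for sm in p.sms]
        smv.score_submovements(sms, basis)
        return smv.assemble_feature_vector(
            ai_features=ai_feats,
            directionality_features=dir_feats,
            spectral_features=spectral,
            bout_features=bout_feats,
            sm_kin_features=smv.sm_kinematic_features(sms),
            sm_pc_features=smv.sm_pc_score_features(sms),
            n_bouts=int(sum(p.n_bouts for p in pds)),
            n_submovements=len(sms),
            subject_id=subject_id,
            site=self.recording.site,
            period=period_label,
        )
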