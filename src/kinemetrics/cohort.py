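"""Synthetic cohort generator with known ground truth.

A latent severity theta in [0, 1] (0 = healthy) drives every modality:

* **Wearable recordings** — multi-day triaxial accelerometry in which daytime
  activity bouts are superpositions of minimum-jerk submovement pulses whose
  amplitude shrinks and whose rate falls as theta grows ("smaller, slower,
  less powerful" movement), riding on low-level ambient motion, a slowly
  rotating gravity vector and white sensor noise.  Nights are gravity plus
  noise only.
* **Mouse sessions** — rounds of point-and-click trials whose trajectories
  are jittered minimum-jerk paths with theta-dependent tremor, pauses,
  overshoot and slower Fitts-law timing.
* **Clinical scores** — each scale is a noisy monotone function of theta,
  clipped to its remote-assessment range (SARA 0-36, BARS 0-30,
  MDS-UPDRS III 0-108, PROM-Ataxia 0-280).

Every synthesized pulse, bout, night boundary and injected mouse pause is
recorded in a :class:`GroundTruth` object so downstream extractors can be
validated against the construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from . import minjerk
from .mouse import MouseSession, MouseTrial
from .preprocess import SECONDS_PER_DAY, AccelRecording

__all__ = [
    "SubjectSpec",
    "ClinicalScores",
    "GroundTruth",
    "WearableGenParams",
    "MouseGenParams",
    "ScoreGenParams",
    "generate_recording",
    "generate_mouse_session",
    "generate_clinical_scores",
    "make_subject_specs",
]


@dataclass
class SubjectSpec:
    """One synthetic participant: latent severity and simulation bookkeeping."""

    subject_id: str
    severity: float
    group: str  # control | preataxic | ataxic
    rng_seed: int
    days: int = 6
    within_subject_sd: float = 0.02

    def __post_init__(self) -> None:
        if not (0.0 <= self.severity <= 1.0):
            raise ValueError(f"severity must be in [0, 1]; got {self.severity}")
        if self.days < 1:
            raise ValueError("days must be >= 1")
        if self.within_subject_sd < 0:
            raise ValueError("within_subject_sd must be >= 0")
        if self.group not in ("control", "preataxic", "ataxic"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.group == "control" and self.severity != 0.0:
            raise ValueError("control subjects must have severity 0")

    def theta_by_day(self, rng: np.random.Generator) -> np.ndarray:
        """Daily latent severity: theta plus day-to-day fluctuation, in [0, 1]."""
        drift = rng.normal(0.0, self.within_subject_sd, size=self.days + 1)
        return np.clip(self.severity + drift, 0.0, 1.0)


@dataclass
class ClinicalScores:
    """Simulated remote-assessment scores, clipped to their scale ranges."""

    sara_total: float      # 0-36 (remote version, sitting item excluded)
    bars_total: float      # 0-30
    updrs3_total: float    # 0-108 (remote version, rigidity items excluded)
    prom_total: float      # 0-280
    subscores: dict[str, float] = field(default_factory=dict)

    RANGES = {
        "sara_total": 36.0,
        "bars_total": 30.0,
        "updrs3_total": 108.0,
        "prom_total": 280.0,
    }

    def __post_init__(self) -> None:
        for name, hi in self.RANGES.items():
            v = getattr(self, name)
            if not (0.0 <= v <= hi):
                raise ValueError(f"{name}={v} outside [0, {hi}]")


@dataclass
class GroundTruth:
    """Everything the generator decided, for traceability in tests."""

    theta_by_day: np.ndarray
    bout_schedule: pd.DataFrame      # day, start_s, end_s (recording clock)
    pulses: pd.DataFrame             # day, bout, axis, t0, distance, duration, sign
    nights: list[tuple[float, float]]  # recording-clock night intervals, s
    bout_rotations: list[np.ndarray] = field(default_factory=list)
    mouse_pauses: pd.DataFrame | None = None  # trial, t_frac, duration_s


# ---------------------------------------------------------------------------
# Wearable recording generator


@dataclass
class WearableGenParams:
    """Knobs of the wearable signal model (defaults = study conditions)."""

    rate_hz: float = 100.0
    day_s: float = SECONDS_PER_DAY   # compressed synthetic days supported
    day_fraction: float = 2.0 / 3.0  # 16-h day / 8-h night
    noise_sd: float = 0.03           # white sensor noise, m/s^2 per axis
    ambient_sd: float = 0.04         # low-frequency ambient motion, m/s^2
    gravity: float = 9.81
    bout_gap_mean_s: float = 120.0   # mean daytime gap between bouts
    bout_dur_range_s: tuple[float, float] = (5.0, 15.0)
    # Pulses are parameterized by peak speed (the disease-scaled magnitude);
    # distance follows as L = (8/15) v_peak D for a minimum-jerk pulse.
    pulse_peak_speed_range_ms: tuple[float, float] = (0.15, 1.0)
    pulse_duration_range_s: tuple[float, float] = (0.10, 0.45)
    pulse_gap_range_s: tuple[float, float] = (0.10, 0.50)
    pc2_scale: float = 0.5           # secondary-direction amplitude ratio
    amp_coef: float = 0.6            # amplitude shrink: L *= (1 - amp_coef*theta)
    rate_coef: float = 0.5           # gaps grow: gap *= (1 + rate_coef*theta)
    dur_coef: float = 0.4            # pulses lengthen: D *= (1 + dur_coef*theta)
    tremor_sd: float = 0.3           # in-bout 3-8 Hz tremor at theta=1, m/s^2
    # Movement decomposition: probability that a pulse carries an overlapping
    # same-sign echo subpulse grows with severity (segmented ataxic movement).
    doublet_coef: float = 0.7
    ambient_sev_coef: float = 0.25   # ambient shrink, kept above the rest floor
    wrist_scale: float = 0.8         # wrist pulses slightly smaller than ankle


def generate_recording(
    spec: SubjectSpec,
    site: str = "ankle",
    params: WearableGenParams | None = None,
    return_truth: bool = False,
):
    """Synthesize a multi-day triaxial recording for one subject and site.

    The recording starts mid-day and spans ``days + 0.5`` 24-h periods, so
    the first full night is interior and anchors day segmentation.  Returns
    the :class:`AccelRecording`, plus the :class:`GroundTruth` when
    ``return_truth`` is set.
    """
    p = params or WearableGenParams()
    if site not in ("wrist", "ankle"):
        raise ValueError(f"unknown site {site!r}")
    rng = np.random.default_rng([spec.rng_seed, 0 if site == "ankle" else 1])
    theta_day = spec.theta_by_day(rng)

    day_len = p.day_fraction * p.day_s
    t0 = 0.5 * day_len  # recording starts mid-day
    total_s = (spec.days + 0.5) * p.day_s
    n = int(round(total_s * p.rate_hz))
    t_abs0 = t0  # absolute clock of first sample
    site_scale = 1.0 if site == "ankle" else p.wrist_scale

    samples = rng.normal(0.0, p.noise_sd, size=(n, 3)) if p.noise_sd > 0 else np.zeros((n, 3))

    # Slowly rotating gravity (period ~ hours, far below the 0.1 Hz cut-off).
    tt = t_abs0 + np.arange(n) / p.rate_hz
    pol = 0.4 + 0.25 * np.sin(2.0 * np.pi * tt / (p.day_s / 3.0))
    azi = 2.0 * np.pi * tt / (p.day_s / 4.0)
    samples[:, 0] += p.gravity * np.sin(pol) * np.cos(azi)
    samples[:, 1] += p.gravity * np.sin(pol) * np.sin(azi)
    samples[:, 2] += p.gravity * np.cos(pol)

    # Daytime intervals on the recording clock, with their period index.
    day_intervals = []
    nights = []
    k = 0
    while k * p.day_s < t_abs0 + total_s:
        a, b = k * p.day_s, k * p.day_s + day_len
        na, nb = b, (k + 1) * p.day_s
        a, b = max(a, t_abs0), min(b, t_abs0 + total_s)
        if b > a:
            day_intervals.append((k, a - t_abs0, b - t_abs0))
        na, nb = max(na, t_abs0), min(nb, t_abs0 + total_s)
        if nb > na:
            nights.append((na - t_abs0, nb - t_abs0))
        k += 1

    # Ambient daytime motion: band-limited noise, amplitude shrinking with theta.
    if p.ambient_sd > 0:
        sos = signal.butter(2, 2.0, btype="low", fs=p.rate_hz, output="sos")
        for k, a, b in day_intervals:
            ia, ib = int(round(a * p.rate_hz)), int(round(b * p.rate_hz))
            th = theta_day[min(k, spec.days)]
            raw = rng.normal(0.0, 1.0, size=(ib - ia, 3))
            amb = signal.sosfiltfilt(sos, raw, axis=0)
            std = amb.std(axis=0)
            std[std == 0] = 1.0
            amb = amb / std * p.ambient_sd * (1.0 - p.ambient_sev_coef * th)
            samples[ia:ib] += amb

    # Activity bouts made of minimum-jerk pulses (+ in-bout action tremor).
    bout_rows, pulse_rows, rotations = [], [], []
    bout_id = 0
    tremor_sos = (
        signal.butter(2, [3.0, 8.0], btype="bandpass", fs=p.rate_hz, output="sos")
        if p.tremor_sd > 0
        else None
    )
    for k, a, b in day_intervals:
        th = theta_day[min(k, spec.days)]
        gap_mean = p.bout_gap_mean_s * (1.0 + p.rate_coef * th)
        t = a + 2.0 + rng.uniform(0.0, gap_mean)
        while True:
            dur = rng.uniform(*p.bout_dur_range_s)
            if t + dur > b - 2.0:
                break
            rot = _random_rotation(rng)
            rotations.append(rot)
            bout_rows.append({"day": k, "bout": bout_id, "start_s": t, "end_s": t + dur})
            for axis in (0, 1):
                scale = site_scale * (p.pc2_scale if axis == 1 else 1.0)
                tp = t + rng.uniform(0.0, 0.3)
                while True:
                    D = rng.uniform(*p.pulse_duration_range_s) * (
                        1.0 + p.dur_coef * th
                    )
                    if tp + D > t + dur:
                        break
                    v_peak = rng.uniform(*p.pulse_peak_speed_range_ms) * scale
                    v_peak *= 1.0 - p.amp_coef * th
                    L = (8.0 / 15.0) * v_peak * D
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    _add_pulse(samples, p.rate_hz, tp, L, D, sign, rot[:, axis])
                    pulse_rows.append(
                        {
                            "day": k,
                            "bout": bout_id,
                            "axis": axis,
                            "t0": tp,
                            "distance": L,
                            "duration": D,
                            "sign": sign,
                        }
                    )
                    t_end = tp + D
                    if rng.random() < p.doublet_coef * th:
                        t_echo = tp + 0.45 * D
                        d_echo, l_echo = 0.7 * D, 0.5 * 0.7 * L
                        _add_pulse(
                            samples, p.rate_hz, t_echo, l_echo, d_echo, sign,
                            rot[:, axis],
                        )
                        pulse_rows.append(
                            {
                                "day": k,
                                "bout": bout_id,
                                "axis": axis,
                                "t0": t_echo,
                                "distance": l_echo,
                                "duration": d_echo,
                                "sign": sign,
                            }
                        )
                        t_end = max(t_end, t_echo + d_echo)
                    tp = t_end + rng.uniform(*p.pulse_gap_range_s) * (
                        1.0 + p.rate_coef * th
                    )
            if tremor_sos is not None and th > 0:
                ia = int(round(t * p.rate_hz))
                ib = min(int(round((t + dur) * p.rate_hz)), n)
                raw = rng.normal(0.0, 1.0, size=(ib - ia, 2))
                trem = signal.sosfiltfilt(tremor_sos, raw, axis=0)
                std = trem.std(axis=0)
                std[std == 0] = 1.0
                trem = trem / std * (p.tremor_sd * th * site_scale)
                trem[:, 1] *= p.pc2_scale
                samples[ia:ib] += trem @ rot[:, :2].T
            bout_id += 1
            t += dur + rng.uniform(0.5, 1.5) * gap_mean

    rec = AccelRecording(
        samples=samples,
        rate_hz=p.rate_hz,
        site=site,
        start_s=t0,
        day_s=p.day_s,
        meta={"subject_id": spec.subject_id, "severity": spec.severity},
    )
    if not return_truth:
        return rec
    truth = GroundTruth(
        theta_by_day=theta_day,
        bout_schedule=pd.DataFrame(
            bout_rows, columns=["day", "bout", "start_s", "end_s"]
        ),
        pulses=pd.DataFrame(
            pulse_rows,
            columns=["day", "bout", "axis", "t0", "distance", "duration", "sign"],
        ),
        nights=nights,
        bout_rotations=rotations,
    )
    return rec, truth


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    return q


def _add_pulse(
    samples: np.ndarray,
    rate_hz: float,
    t0: float,
    distance: float,
    duration: float,
    sign: float,
    direction: np.ndarray,
) -> None:
    i0 = int(np.ceil(t0 * rate_hz))
    i1 = int(np.floor((t0 + duration) * rate_hz))
    i0, i1 = max(i0, 0), min(i1, samples.shape[0] - 1)
    if i1 <= i0:
        return
    t = np.arange(i0, i1 + 1) / rate_hz - t0
    a = sign * minjerk.acceleration(t, distance, duration)
    samples[i0 : i1 + 1] += a[:, None] * direction[None, :]


# ---------------------------------------------------------------------------
# Mouse session generator


@dataclass
class MouseGenParams:
    """Knobs of the point-and-click trajectory model."""

    rate_hz: float = 60.0
    screen: tuple[int, int] = (1920, 1080)
    target_radius_px: float = 30.0
    margin_px: float = 150.0
    fitts_a_s: float = 0.35
    fitts_b_s: float = 0.25
    slow_coef: float = 1.5           # movement time *= (1 + slow_coef*theta)
    jitter_coef: float = 0.06        # perpendicular wander, fraction of distance
    tremor_px: float = 4.0           # high-frequency tremor amplitude at theta=1
    pause_prob_coef: float = 0.6     # per-opportunity pause probability coef
    pause_opportunities: int = 3
    pause_dur_range_s: tuple[float, float] = (0.15, 0.6)
    overshoot_prob_coef: float = 0.6
    overshoot_scale: float = 2.0     # overshoot distance in target radii at theta=1
    reaction_s: tuple[float, float] = (0.05, 0.20)  # base + theta-slope
    dwell_s: tuple[float, float] = (0.15, 0.35)
    click_dur_s: tuple[float, float] = (0.08, 0.12)


def generate_mouse_session(
    spec: SubjectSpec,
    rounds: int = 8,
    targets_per_round: int = 9,
    params: MouseGenParams | None = None,
    session_index: int = 0,
    return_truth: bool = False,
):
    """Synthesize one point-and-click session (default 8 rounds x 9 targets).

    The first target of each round is uncued (session-initiating) and is
    excluded from analysis, leaving 64 cued trials in the default layout.
    Per-session severity is theta plus the subject's day-to-day fluctuation.
    """
    p = params or MouseGenParams()
    if rounds < 1 or targets_per_round < 2:
        raise ValueError("need rounds >= 1 and targets_per_round >= 2")
    rng = np.random.default_rng([spec.rng_seed, 100 + session_index])
    th = float(
        np.clip(spec.severity + rng.normal(0.0, spec.within_subject_sd), 0.0, 1.0)
    )
    w, h = p.screen

    pause_rows = []
    rounds_out: list[list[MouseTrial]] = []
    t = 0.0
    pos = np.array([w / 2.0, h / 2.0])
    trial_idx = 0
    for _ in range(rounds):
        trials: list[MouseTrial] = []
        for ti in range(targets_per_round):
            target = np.array(
                [
                    rng.uniform(p.margin_px, w - p.margin_px),
                    rng.uniform(p.margin_px, h - p.margin_px),
                ]
            )
            if not (0 <= target[0] <= w and 0 <= target[1] <= h):
                raise ValueError("target outside screen bounds")
            cued = ti > 0
            trial, pos, t, injected = _make_trial(
                pos, target, t, th if cued else 0.0, p, rng, cued
            )
            trials.append(trial)
            for tau, dur in injected:
                pause_rows.append(
                    {"trial": trial_idx, "t_frac": tau, "duration_s": dur}
                )
            trial_idx += 1
        rounds_out.append(trials)

    session = MouseSession(
        session_id=f"{spec.subject_id}-s{session_index}",
        screen=p.screen,
        rounds=rounds_out,
        rate_hz=p.rate_hz,
        meta={"subject_id": spec.subject_id, "session_index": session_index},
    )
    if not return_truth:
        return session
    truth = pd.DataFrame(pause_rows, columns=["trial", "t_frac", "duration_s"])
    return session, truth


def _make_trial(
    start: np.ndarray,
    target: np.ndarray,
    t0: float,
    th: float,
    p: MouseGenParams,
    rng: np.random.Generator,
    cued: bool,
) -> tuple[MouseTrial, np.ndarray, float, list[tuple[float, float]]]:
    dt = 1.0 / p.rate_hz
    cue_t = t0
    dist = float(np.linalg.norm(target - start))
    dist = max(dist, 1.0)
    u = (target - start) / dist
    nvec = np.array([-u[1], u[0]])

    # Overshoot: aim past the centre, then correct back.
    overshoot = 0.0
    if th > 0 and rng.random() < p.overshoot_prob_coef * th:
        overshoot = p.overshoot_scale * th * p.target_radius_px * rng.uniform(0.5, 1.0)

    mt = (p.fitts_a_s + p.fitts_b_s * np.log2(dist / p.target_radius_px + 1.0)) * (
        1.0 + p.slow_coef * th
    )
    n_react = max(1, int(round((p.reaction_s[0] + p.reaction_s[1] * th) / dt)))
    n_move = max(8, int(round(mt / dt)))
    tau = np.linspace(0.0, 1.0, n_move)
    s_prof = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    main_end = target + u * overshoot
    path = start[None, :] + (main_end - start)[None, :] * s_prof[:, None]

    if th > 0:
        env = np.sin(np.pi * tau)
        wander = np.zeros(n_move)
        for kk in range(1, 4):
            wander += rng.normal(0.0, 1.0) * np.sin(np.pi * kk * tau) / kk
        path += nvec[None, :] * (p.jitter_coef * th * dist / 3.0 * wander)[:, None]
        tremor = rng.normal(0.0, p.tremor_px * th, size=(n_move, 2))
        path += tremor * env[:, None]

    if overshoot > 0:
        n_corr = max(6, int(round(0.25 * (1.0 + th) / dt)))
        tau_c = np.linspace(0.0, 1.0, n_corr)
        s_c = 10 * tau_c**3 - 15 * tau_c**4 + 6 * tau_c**5
        corr = main_end[None, :] + (target - main_end)[None, :] * s_c[:, None]
        path = np.vstack([path, corr[1:]])

    # Injected pauses: freeze the cursor mid-movement.
    injected: list[tuple[float, float]] = []
    if th > 0:
        n_p = rng.binomial(p.pause_opportunities, min(1.0, p.pause_prob_coef * th))
        for tau_p in sorted(rng.uniform(0.2, 0.8, size=n_p)):
            dur = rng.uniform(*p.pause_dur_range_s)
            idx = int(tau_p * len(path))
            hold = np.repeat(path[idx : idx + 1], int(round(dur / dt)), axis=0)
            path = np.vstack([path[:idx], hold, path[idx:]])
            injected.append((tau_p, dur))

    # Verification dwell inside the target, then the click.
    inside = target + rng.uniform(-0.3, 0.3, size=2) * p.target_radius_px / 2.0
    path[-1] = inside
    n_dwell = max(2, int(round((p.dwell_s[0] + p.dwell_s[1] * th) / dt)))
    path = np.vstack([path, np.repeat(inside[None, :], n_dwell, axis=0)])

    times = cue_t + dt * np.arange(n_react + len(path))
    xy = np.vstack([np.repeat(start[None, :], n_react, axis=0), path])
    down_t = float(times[-1] + dt)
    click_dur = p.click_dur_s[0] + p.click_dur_s[1] * th + rng.uniform(0.0, 0.02)
    slip = rng.normal(0.0, 1.0 + 3.0 * th, size=2)
    buttons = [
        {"type": "down", "t": down_t, "x": float(inside[0]), "y": float(inside[1])},
        {
            "type": "up",
            "t": down_t + click_dur,
            "x": float(inside[0] + slip[0]),
            "y": float(inside[1] + slip[1]),
        },
    ]
    samples = np.column_stack([times, xy])
    trial = MouseTrial(
        target_center=target,
        target_radius=p.target_radius_px,
        cue_t=cue_t,
        samples=samples,
        buttons=buttons,
        cued=cued,
    )
    t_next = down_t + click_dur + 0.3
    return trial, inside.copy(), t_next, injected


# ---------------------------------------------------------------------------
# Clinical scores


@dataclass
class ScoreGenParams:
    """Noise model of the simulated clinician / patient-reported scores."""

    sara_noise_sd: float = 1.5
    bars_noise_sd: float = 1.25
    updrs_noise_sd: float = 3.0
    prom_noise_sd: float = 12.0
    updrs_slope: float = 0.5   # parkinsonian signs are partial in ataxia
    prom_slope: float = 0.65


def generate_clinical_scores(
    spec: SubjectSpec, params: ScoreGenParams | None = None
) -> ClinicalScores:
    """Noisy monotone mapping theta -> clinical scales, clipped to range.

    Preataxic subjects are truncated below the SARA < 3 criterion that
    defines the group.
    """
    p = params or ScoreGenParams()
    rng = np.random.default_rng([spec.rng_seed, 7])
    th = spec.severity

    def scale(range_max: float, slope: float, sd: float) -> float:
        return float(np.clip(range_max * slope * th + rng.normal(0.0, sd), 0.0, range_max))

    sara = scale(36.0, 1.0, p.sara_noise_sd)
    if spec.group == "preataxic":
        sara = min(sara, 2.95)
    bars = scale(30.0, 1.0, p.bars_noise_sd)
    updrs = scale(108.0, p.updrs_slope, p.updrs_noise_sd)
    prom = scale(280.0, p.prom_slope, p.prom_noise_sd)
    sub = {
        "sara_gait": scale(8.0, 1.0, p.sara_noise_sd / 4.0),
        "sara_fnf": scale(4.0, 1.0, p.sara_noise_sd / 6.0),
        "bars_gait": scale(8.0, 1.0, p.bars_noise_sd / 4.0),
        "bars_fnf": scale(4.0, 1.0, p.bars_noise_sd / 6.0),
        "prom_gait": scale(48.0, p.prom_slope, p.prom_noise_sd / 4.0),
        "prom_arm": scale(60.0, p.prom_slope, p.prom_noise_sd / 4.0),
        "prom_motor": scale(112.0, p.prom_slope, p.prom_noise_sd / 2.0),
    }
    return ClinicalScores(
        sara_total=sara,
        bars_total=bars,
        updrs3_total=updrs,
        prom_total=prom,
        subscores=sub,
    )


# ---------------------------------------------------------------------------
# Cohort assembly


def make_subject_specs(
    n_subjects: int = 40,
    n_controls: int = 8,
    n_preataxic: int = 4,
    days: int = 6,
    seed: int = 0,
    within_subject_sd: float = 0.02,
) -> list[SubjectSpec]:
    """Deterministic cohort layout: controls (theta=0), preataxic (theta small,
    SARA < 3), and ataxic subjects with severities spread over (0.1, 0.95)."""
    if n_controls + n_preataxic > n_subjects:
        raise ValueError("more controls+preataxic than subjects")
    rng = np.random.default_rng([seed, 999])
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_subjects)]
    specs = []
    n_ataxic = n_subjects - n_controls - n_preataxic
    sev_ataxic = np.sort(rng.uniform(0.1, 0.95, size=n_ataxic))
    sev_pre = rng.uniform(0.02, 0.06, size=n_preataxic)
    i = 0
    for k in range(n_controls):
        specs.append(
            SubjectSpec(f"C{k:02d}", 0.0, "control", child_seeds[i], days, within_subject_sd)
        )
        i += 1
    for k in range(n_preataxic):
        specs.append(
            SubjectSpec(
                f"P{k:02d}", float(sev_pre[k]), "preataxic", child_seeds[i], days,
                within_subject_sd,
            )
        )
        i += 1
    for k in range(n_ataxic):
        specs.append(
            SubjectSpec(
                f"A{k:02d}", float(sev_ataxic[k]), "ataxic", child_seeds[i], days,
                within_subject_sd,
            )
        )
        i += 1
    return specs
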