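"""Point-and-click (Hevelius-style) session logs and their 33 features.

A session consists of rounds of targets; the participant clicks each target
as soon as it appears.  The first target of every round only initiates the
round and is excluded, so an 8-round x 9-target session yields 64 analyzed
(cued) trials.  Per cued trial the cursor trajectory is reduced to timing,
speed, smoothness and accuracy metrics; per session these are aggregated
(mean / CV / SD across trials) into 33 canonical features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "MouseTrial",
    "MouseSession",
    "TrialMetrics",
    "parse_session",
    "write_session",
    "trial_metrics",
    "session_features",
    "median_session_features",
    "MOUSE_FEATURE_NAMES",
]

#: Pause: speed below max(floor, frac * trial peak speed) for >= min duration.
PAUSE_SPEED_FRAC = 0.05
PAUSE_SPEED_FLOOR = 10.0  # px/s
PAUSE_MIN_DURATION_S = 0.1
#: Submovement split: local speed minima below this fraction of peak speed.
SM_SADDLE_FRAC = 0.10
#: Cut-off separating "noise" from "force" band power of the speed profile.
NOISE_FORCE_SPLIT_HZ = 4.0
SPEED_SMOOTH_SAMPLES = 5


@dataclass
class MouseTrial:
    target_center: np.ndarray     # (2,) px
    target_radius: float          # px
    cue_t: float                  # s
    samples: np.ndarray           # (n, 3): t, x, y
    buttons: list[dict]           # {"type": "down"|"up", "t":, "x":, "y":}
    cued: bool = True


@dataclass
class MouseSession:
    session_id: str
    screen: tuple[int, int]
    rounds: list[list[MouseTrial]]
    rate_hz: float = 60.0
    meta: dict = field(default_factory=dict)

    def cued_trials(self) -> list[MouseTrial]:
        return [t for rnd in self.rounds for t in rnd if t.cued]


def write_session(session: MouseSession, path: str | Path) -> None:
    """Serialize a session to the versioned JSON log schema."""
    doc = {
        "schema": "kinemetrics-mouse-log/1",
        "session_id": session.session_id,
        "screen": list(session.screen),
        "rate_hz": session.rate_hz,
        "meta": session.meta,
        "rounds": [
            {
                "trials": [
                    {
                        "target": {
                            "x": float(t.target_center[0]),
                            "y": float(t.target_center[1]),
                            "radius": float(t.target_radius),
                        },
                        "cue_t": float(t.cue_t),
                        "cued": bool(t.cued),
                        "samples": np.asarray(t.samples, dtype=float).tolist(),
                        "buttons": t.buttons,
                    }
                    for t in rnd
                ]
            }
            for rnd in session.rounds
        ],
    }
    Path(path).write_text(json.dumps(doc))


def parse_session(log: str | Path | dict) -> MouseSession:
    """Parse and validate a session log (path or already-loaded dict).

    Enforces strictly increasing cursor timestamps and exactly one
    successful (inside-target) button-down per completed trial; incomplete
    trailing trials are dropped and counted in ``meta['n_dropped']``.
    """
    if not isinstance(log, dict):
        log = json.loads(Path(log).read_text())
    rounds: list[list[MouseTrial]] = []
    n_dropped = 0
    for ri, rnd in enumerate(log["rounds"]):
        trials: list[MouseTrial] = []
        for ti, tr in enumerate(rnd["trials"]):
            where = f"round {ri} trial {ti}"
            samples = np.asarray(tr["samples"], dtype=float)
            if samples.ndim != 2 or samples.shape[1] != 3:
                raise ValueError(f"{where}: samples must be [t, x, y] rows")
            if np.any(np.diff(samples[:, 0]) <= 0):
                raise ValueError(f"{where}: cursor timestamps not strictly increasing")
            target = np.array([tr["target"]["x"], tr["target"]["y"]], dtype=float)
            radius = float(tr["target"]["radius"])
            downs = [
                b
                for b in tr["buttons"]
                if b["type"] == "down"
                and np.hypot(b["x"] - target[0], b["y"] - target[1]) <= radius
            ]
            if len(downs) != 1:
                # Trailing trial never completed (no successful click): drop.
                n_dropped += 1
                continue
            trials.append(
                MouseTrial(
                    target_center=target,
                    target_radius=radius,
                    cue_t=float(tr["cue_t"]),
                    samples=samples,
                    buttons=list(tr["buttons"]),
                    cued=bool(tr.get("cued", True)),
                )
            )
        rounds.append(trials)
    return MouseSession(
        session_id=str(log.get("session_id", "")),
        screen=tuple(log.get("screen", (0, 0))),
        rounds=rounds,
        rate_hz=float(log.get("rate_hz", 60.0)),
        meta=dict(log.get("meta", {}), n_dropped=n_dropped),
    )


# ---------------------------------------------------------------------------
# Per-trial metrics

@dataclass
class TrialMetrics:
    movement_time_s: float = np.nan
    execution_time_s: float = np.nan
    verification_time_s: float = np.nan
    execution_time_wo_pauses_s: float = np.nan
    n_pauses: float = np.nan
    longest_pause_s: float = np.nan
    max_speed: float = np.nan
    max_accel: float = np.nan
    normalized_jerk: float = np.nan
    normalized_jerk_wo_pauses: float = np.nan
    click_duration_s: float = np.nan
    direction_changes: float = np.nan
    orthogonal_direction_changes: float = np.nan
    task_axis_crossings: float = np.nan
    max_axis_deviation: float = np.nan
    movement_error: float = np.nan
    movement_offset: float = np.nan
    movement_variability: float = np.nan
    dist_to_target_end_main_sm: float = np.nan
    target_reentries: float = np.nan
    click_slip: float = np.nan
    frac_dist_main_sm: float = np.nan
    frac_main_sm_accelerating: float = np.nan
    n_submovements: float = np.nan
    main_sm_share: float = np.nan
    noise_to_force_ratio: float = np.nan


_METRIC_FIELDS = list(TrialMetrics.__dataclass_fields__)


def _smooth(x: np.ndarray, k: int = SPEED_SMOOTH_SAMPLES) -> np.ndarray:
    if len(x) < k or k <= 1:
        return x.astype(float)
    kernel = np.ones(k) / k
    pad = k // 2
    xp = np.pad(x.astype(float), pad, mode="edge")
    return np.convolve(xp, kernel, mode="valid")[: len(x)]


def _sign_changes(x: np.ndarray, tol: float = 1e-9) -> int:
    s = np.sign(x)
    s[np.abs(x) <= tol] = 0
    s = s[s != 0]
    return int(np.sum(s[1:] != s[:-1])) if s.size > 1 else 0


def _resample_by_arclength(xy: np.ndarray, n: int = 100) -> np.ndarray:
    ds = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(ds)])
    if s[-1] <= 0:
        return np.repeat(xy[:1], n, axis=0)
    grid = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(grid, s, xy[:, i]) for i in range(2)])


def trial_metrics(trial: MouseTrial) -> "TrialMetrics":
    """Reduce one cued trial's trajectory to its kinematic metrics.

    Execution ends at the cursor's final entry into the target disc before
    the successful button-down; verification is final entry -> button-down,
    so execution + verification = movement time exactly.  Metrics that need
    a target entry are NaN when the cursor never entered before the click.
    """
    t = trial.samples[:, 0]
    if len(t) < 5:
        raise ValueError("trial needs >= 5 cursor samples")
    xy = trial.samples[:, 1:3]
    down = next(b for b in trial.buttons if b["type"] == "down")
    ups = [b for b in trial.buttons if b["type"] == "up" and b["t"] >= down["t"]]
    up = ups[0] if ups else None

    m = {f: np.nan for f in _METRIC_FIELDS}
    m["movement_time_s"] = down["t"] - trial.cue_t
    m["click_duration_s"] = (up["t"] - down["t"]) if up else np.nan
    m["click_slip"] = (
        float(np.hypot(up["x"] - down["x"], up["y"] - down["y"])) if up else np.nan
    )

    # Target entries up to the click.
    pre = t <= down["t"]
    inside = (
        np.linalg.norm(xy - trial.target_center, axis=1) <= trial.target_radius
    ) & pre
    entries = np.flatnonzero(inside & ~np.roll(inside, 1))
    if inside.size and inside[0]:
        entries = np.concatenate([[0], entries[entries != 0]])
    if entries.size == 0:
        return TrialMetrics(**m)  # no entry before click: timing split undefined
    final_entry = int(entries[-1])
    m["target_reentries"] = float(entries.size - 1)
    m["execution_time_s"] = t[final_entry] - trial.cue_t
    m["verification_time_s"] = m["movement_time_s"] - m["execution_time_s"]

    # Execution-phase kinematics from smoothed positions.
    ex = slice(int(np.searchsorted(t, trial.cue_t)), final_entry + 1)
    te, pe = t[ex], xy[ex]
    if len(te) < 5:
        return TrialMetrics(**m)
    sx, sy = _smooth(pe[:, 0]), _smooth(pe[:, 1])
    vx, vy = np.gradient(sx, te), np.gradient(sy, te)
    speed = np.hypot(vx, vy)
    ax_, ay_ = np.gradient(vx, te), np.gradient(vy, te)
    accel = np.hypot(ax_, ay_)
    m["max_speed"] = float(speed.max())
    m["max_accel"] = float(accel.max())

    # Pauses.  The moving-average smoothing erodes (k-1)/2 samples from each
    # edge of a stationary run; pad durations back by the known bias.
    thresh = max(PAUSE_SPEED_FLOOR, PAUSE_SPEED_FRAC * speed.max())
    slow = speed < thresh
    dt_med = float(np.median(np.diff(te)))
    pad = SPEED_SMOOTH_SAMPLES - 1
    pauses = []
    for a, b in _bool_runs(slow):
        dur = (b - a + pad) * dt_med
        if dur >= PAUSE_MIN_DURATION_S:
            pauses.append((a, b, dur))
    m["n_pauses"] = float(len(pauses))
    m["longest_pause_s"] = max((p[2] for p in pauses), default=0.0)
    total_pause = sum(p[2] for p in pauses)
    m["execution_time_wo_pauses_s"] = m["execution_time_s"] - total_pause

    # Normalized jerk (vector jerk; dimensionless, scale-invariant).
    m["normalized_jerk"] = _normalized_jerk(te, vx, vy)
    if pauses:
        keep = np.ones(len(te), dtype=bool)
        for a, b, _ in pauses:
            keep[a:b] = False
        if keep.sum() >= 5:
            # Uniform sampling: stitch the kept samples onto a regular grid.
            tk = np.arange(keep.sum()) * float(np.median(np.diff(te)))
            m["normalized_jerk_wo_pauses"] = _normalized_jerk(
                tk, vx[keep], vy[keep]
            )
    else:
        m["normalized_jerk_wo_pauses"] = m["normalized_jerk"]

    # Task-axis geometry.
    start = pe[0]
    axis = trial.target_center - start
    dist = np.linalg.norm(axis)
    if dist > 0:
        u = axis / dist
        nvec = np.array([-u[1], u[0]])
        d_perp = (pe - start) @ nvec
        m["task_axis_crossings"] = float(_sign_changes(d_perp, tol=1e-6))
        m["max_axis_deviation"] = float(np.abs(d_perp).max())
        rs = _resample_by_arclength(pe)
        d_rs = (rs - start) @ nvec
        m["movement_error"] = float(np.abs(d_rs).mean())
        m["movement_offset"] = float(d_rs.mean())
        m["movement_variability"] = float(d_rs.std())
        m["direction_changes"] = float(_sign_changes(vx * u[0] + vy * u[1], tol=1e-6))
        m["orthogonal_direction_changes"] = float(
            _sign_changes(vx * nvec[0] + vy * nvec[1], tol=1e-6)
        )

        # Submovement decomposition of the speed profile.
        sm_bounds = _speed_minima_bounds(speed)
        seg_len, seg_prog = [], []
        for a, b in zip(sm_bounds[:-1], sm_bounds[1:]):
            step = np.linalg.norm(np.diff(pe[a : b + 1], axis=0), axis=1).sum()
            seg_len.append(step)
            seg_prog.append(((pe[b] - pe[a]) @ u))
        m["n_submovements"] = float(len(seg_len))
        if seg_len:
            main = int(np.argmax(seg_len))
            a, b = sm_bounds[main], sm_bounds[main + 1]
            total_len = sum(seg_len)
            m["main_sm_share"] = seg_len[main] / total_len if total_len > 0 else np.nan
            m["frac_dist_main_sm"] = float(np.clip(seg_prog[main] / dist, 0.0, 1.0))
            m["dist_to_target_end_main_sm"] = float(
                np.linalg.norm(pe[b] - trial.target_center)
            )
            seg_speed = speed[a : b + 1]
            if len(seg_speed) > 1:
                m["frac_main_sm_accelerating"] = float(
                    np.mean(np.diff(seg_speed) > 0)
                )

    # Noise-to-force ratio of the speed profile.
    if len(speed) >= 16:
        fs = 1.0 / np.median(np.diff(te))
        f, psd = signal.welch(
            speed - speed.mean(), fs=fs, nperseg=min(len(speed), 256)
        )
        lo = psd[f <= NOISE_FORCE_SPLIT_HZ].sum()
        hi = psd[f > NOISE_FORCE_SPLIT_HZ].sum()
        m["noise_to_force_ratio"] = float(hi / lo) if lo > 0 else np.nan
    return TrialMetrics(**m)


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    m = np.asarray(mask, dtype=bool)
    diff = np.diff(m.astype(int))
    starts = list(np.flatnonzero(diff == 1) + 1)
    ends = list(np.flatnonzero(diff == -1) + 1)
    if m.size and m[0]:
        starts.insert(0, 0)
    if m.size and m[-1]:
        ends.append(m.size)
    return list(zip(starts, ends))


def _normalized_jerk(t: np.ndarray, vx: np.ndarray, vy: np.ndarray) -> float:
    if len(t) < 5:
        return np.nan
    dur = t[-1] - t[0]
    vpeak = np.hypot(vx, vy).max()
    if dur <= 0 or vpeak <= 0:
        return np.nan
    jx = np.gradient(np.gradient(vx, t), t)
    jy = np.gradient(np.gradient(vy, t), t)
    int_j2 = np.trapezoid(jx**2 + jy**2, t)
    return float(np.sqrt(dur**3 / vpeak**2 * int_j2))


def _speed_minima_bounds(speed: np.ndarray) -> list[int]:
    """Submovement boundaries: local speed minima below the saddle threshold."""
    thresh = SM_SADDLE_FRAC * speed.max()
    bounds = [0]
    for i in range(1, len(speed) - 1):
        if (
            speed[i] <= speed[i - 1]
            and speed[i] < speed[i + 1]
            and speed[i] < thresh
            and i - bounds[-1] > 2
        ):
            bounds.append(i)
    bounds.append(len(speed) - 1)
    return bounds


# ---------------------------------------------------------------------------
# Session-level aggregation: the canonical 33 features

#: (canonical name, per-trial metric, aggregator)
_SESSION_SPEC: list[tuple[str, str, str]] = [
    ("movement_time", "movement_time_s", "mean"),
    ("movement_time_cv", "movement_time_s", "cv"),
    ("execution_time", "execution_time_s", "mean"),
    ("execution_time_cv", "execution_time_s", "cv"),
    ("execution_time_wo_pauses", "execution_time_wo_pauses_s", "mean"),
    ("execution_time_wo_pauses_cv", "execution_time_wo_pauses_s", "cv"),
    ("verification_time", "verification_time_s", "mean"),
    ("verification_time_sd", "verification_time_s", "sd"),
    ("n_pauses", "n_pauses", "mean"),
    ("longest_pause", "longest_pause_s", "mean"),
    ("max_speed", "max_speed", "mean"),
    ("max_speed_cv", "max_speed", "cv"),
    ("max_accel", "max_accel", "mean"),
    ("max_accel_cv", "max_accel", "cv"),
    ("normalized_jerk", "normalized_jerk", "mean"),
    ("normalized_jerk_wo_pauses", "normalized_jerk_wo_pauses", "mean"),
    ("click_duration", "click_duration_s", "mean"),
    ("click_duration_sd", "click_duration_s", "sd"),
    ("direction_changes", "direction_changes", "mean"),
    ("orthogonal_direction_changes", "orthogonal_direction_changes", "mean"),
    ("task_axis_crossings", "task_axis_crossings", "mean"),
    ("max_axis_deviation", "max_axis_deviation", "mean"),
    ("movement_error", "movement_error", "mean"),
    ("movement_offset", "movement_offset", "mean"),
    ("movement_variability", "movement_variability", "mean"),
    ("dist_to_target_end_main_sm", "dist_to_target_end_main_sm", "mean"),
    ("target_reentries", "target_reentries", "mean"),
    ("click_slip", "click_slip", "mean"),
    ("frac_dist_main_sm", "frac_dist_main_sm", "mean"),
    ("frac_main_sm_accelerating", "frac_main_sm_accelerating", "mean"),
    ("n_submovements", "n_submovements", "mean"),
    ("main_sm_share", "main_sm_share", "mean"),
    ("noise_to_force_ratio", "noise_to_force_ratio", "mean"),
]

MOUSE_FEATURE_NAMES: list[str] = [name for name, _, _ in _SESSION_SPEC]
assert len(MOUSE_FEATURE_NAMES) == 33


def session_features(
    session: MouseSession, min_valid_trials: int = 8
) -> dict[str, float]:
    """Aggregate cued-trial metrics into the 33 canonical session features.

    Plain names are across-trial means, ``*_cv`` are SD/mean (population SD,
    NaN when the mean is not positive) and ``*_sd`` are population SDs.
    Raises when fewer than ``min_valid_trials`` cued trials have metrics.
    """
    trials = session.cued_trials()
    metrics = []
    for tr in trials:
        try:
            metrics.append(trial_metrics(tr))
        except ValueError:
            continue
    if len(metrics) < min_valid_trials:
        raise ValueError(
            f"session {session.session_id!r}: only {len(metrics)} valid cued "
            f"trials (need {min_valid_trials})"
        )
    table = pd.DataFrame([vars(tm) for tm in metrics])
    out: dict[str, float] = {}
    for name, metric, agg in _SESSION_SPEC:
        vals = table[metric].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            out[name] = np.nan
            continue
        if agg == "mean":
            out[name] = float(vals.mean())
        elif agg == "sd":
            out[name] = float(vals.std())
        else:  # cv
            mu = vals.mean()
            out[name] = float(vals.std() / mu) if mu > 0 else np.nan
    return out


def median_session_features(
    feature_rows: list[dict[str, float]], split: str = "all"
) -> dict[str, float]:
    """Per-feature median across sessions, or across a session half.

    Halves: first floor(n/2) vs last ceil(n/2) sessions, so 8 sessions split
    4/4 and 6 sessions split 3/3.
    """
    n = len(feature_rows)
    if split == "all":
        rows = feature_rows
    elif split == "first_half":
        rows = feature_rows[: n // 2]
    elif split == "second_half":
        rows = feature_rows[n - (n - n // 2) :]
    else:
        raise ValueError(f"unknown split {split!r}")
    if not rows:
        raise ValueError("no sessions selected")
    table = pd.DataFrame(rows)
    return {name: float(table[name].median()) for name in MOUSE_FEATURE_NAMES}
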