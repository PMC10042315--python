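"""Preprocessing of raw multi-day triaxial accelerometry.

Raw wearable recordings (nominally 100 Hz, m/s^2, one sensor per wear site)
are band-pass filtered to remove gravity and high-frequency sensor noise,
their noise floor is calibrated from quiescent windows, and the multi-day
stream is segmented into consecutive 24-h day/night periods anchored at the
onset of the first full night.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

SECONDS_PER_DAY = 86400.0

__all__ = [
    "AccelRecording",
    "DaySegmentation",
    "bandpass",
    "estimate_noise_variance",
    "segment_days",
    "read_recording_csv",
    "write_recording_csv",
    "read_day_override",
]


@dataclass
class AccelRecording:
    """Uniformly sampled triaxial acceleration time series.

    samples : (n, 3) array, m/s^2
    rate_hz : sampling rate (nominal 100)
    site    : "wrist" or "ankle"
    start_s : wall-clock offset of the first sample, seconds
    day_s   : length of the nominal 24-h period on this recording's clock.
              86400 for real data; synthetic cohorts may use compressed days.
    """

    samples: np.ndarray
    rate_hz: float
    site: str = "ankle"
    start_s: float = 0.0
    day_s: float = SECONDS_PER_DAY
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) array")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.site not in ("wrist", "ankle"):
            raise ValueError(f"unknown wear site {self.site!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def times(self) -> np.ndarray:
        return self.start_s + np.arange(self.n_samples) / self.rate_hz


@dataclass
class DaySegmentation:
    """Consecutive 24-h analysis periods anchored at the first full night.

    periods : list of (start, end) sample-index pairs, each spanning one
              24-h period (at most six are kept)
    nights  : list of (start, end) sample-index pairs of detected nights
    day_intervals : per period, list of (start, end) daytime index pairs
              (the complement of the nights within the period)
    """

    periods: list[tuple[int, int]]
    nights: list[tuple[int, int]]
    day_intervals: list[list[tuple[int, int]]]

    @property
    def n_periods(self) -> int:
        return len(self.periods)

    def daytime_indices(self, periods: Sequence[int] | None = None) -> np.ndarray:
        """Concatenated sample indices of daytime in the selected periods (0-based)."""
        sel = range(self.n_periods) if periods is None else periods
        chunks = [
            np.arange(a, b)
            for p in sel
            for (a, b) in self.day_intervals[p]
        ]
        if not chunks:
            return np.empty(0, dtype=int)
        return np.concatenate(chunks)


def bandpass(
    recording: AccelRecording,
    low_hz: float = 0.1,
    high_hz: float = 20.0,
    order: int = 6,
) -> AccelRecording:
    """Zero-phase Butterworth band-pass, applied per axis.

    A sixth-order band-pass with cut-offs 0.1 and 20 Hz removes the gravity
    (DC) component and high-frequency sensor noise.  The filter is applied
    forward-backward (``sosfiltfilt``) so kinematic timing is not phase
    shifted; the effective magnitude response is therefore |H|^2.
    """
    if not (0.0 < low_hz < high_hz < recording.rate_hz / 2.0):
        raise ValueError(
            f"need 0 < low_hz < high_hz < Nyquist; got {low_hz}, {high_hz} at "
            f"rate {recording.rate_hz}"
        )
    # Edge transients of the low cut-off have time constant ~1/low_hz.
    if recording.duration_s < 3.0 / low_hz:
        raise ValueError(
            f"recording of {recording.duration_s:.1f}s is shorter than three "
            f"filter time constants ({3.0 / low_hz:.1f}s)"
        )
    sos = signal.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=recording.rate_hz, output="sos"
    )
    out = signal.sosfiltfilt(sos, recording.samples, axis=0)
    return AccelRecording(
        samples=out,
        rate_hz=recording.rate_hz,
        site=recording.site,
        start_s=recording.start_s,
        day_s=recording.day_s,
        meta=dict(recording.meta, filtered=True, low_hz=low_hz, high_hz=high_hz),
    )


def estimate_noise_variance(
    recording: AccelRecording, window_s: float = 1.0
) -> np.ndarray:
    """Per-axis sensor-noise variance (m^2/s^4) from the quietest windows.

    The recording is cut into non-overlapping windows; the per-axis sample
    variance is averaged over the windows whose mean variance falls in the
    lowest decile (quiescent periods), then debiased for the chi-square
    selection effect (picking the quietest windows of a white-noise process
    systematically underestimates its variance; the truncated-chi-square
    mean gives the exact Gaussian correction).  For a recording that
    contains real rest this recovers the white-noise floor needed by the
    activity index.
    """
    from scipy import stats as _sps

    w = int(round(window_s * recording.rate_hz))
    n_win = recording.n_samples // w
    if n_win < 60:
        raise ValueError(f"need >= 60 windows of {window_s}s; have {n_win}")
    x = recording.samples[: n_win * w].reshape(n_win, w, 3)
    var = x.var(axis=1)  # (n_win, 3)
    mean_var = var.mean(axis=1)
    k = max(1, int(np.ceil(0.1 * n_win)))
    idx = np.argsort(mean_var)[:k]
    # If even the quietest decile is as active as the rest, the estimate is
    # an upper bound on the noise floor; warn but still return it.
    if np.median(mean_var) > 0 and mean_var[idx].mean() > 0.5 * np.median(mean_var):
        warnings.warn(
            "no clearly quiescent windows found; noise variance may be "
            "overestimated",
            stacklevel=2,
        )
    # E[chi2_nu/nu | below the q-quantile] = P(chi2_{nu+2} <= t) / q.
    nu = 3 * (w - 1)
    q = k / n_win
    t = _sps.chi2.ppf(q, nu)
    trunc_mean = _sps.chi2.cdf(t, nu + 2) / q
    return var[idx].mean(axis=0) / trunc_mean


def _smooth_profile(values: np.ndarray, smooth_windows: int) -> np.ndarray:
    """Running median of an activity profile (odd kernel, edge-padded)."""
    k = max(1, smooth_windows)
    if k % 2 == 0:
        k += 1
    if k == 1:
        return values.astype(float)
    padded = np.pad(values.astype(float), k // 2, mode="edge")
    return signal.medfilt(padded, kernel_size=k)[k // 2 : k // 2 + len(values)]


def segment_days(
    recording: AccelRecording,
    ai_values: np.ndarray,
    ai_window_s: float = 1.0,
    min_night_h: float = 4.0,
    max_night_h: float = 14.0,
    smooth_h: float = 1.0,
    max_periods: int = 6,
    override: Sequence[tuple[float, float]] | None = None,
) -> DaySegmentation:
    """Detect nights and cut the recording into 24-h analysis periods.

    Nights are maximal runs of a smoothed (running-median, ``smooth_h``)
    activity-index profile below an adaptive threshold, lasting between
    ``min_night_h`` and ``max_night_h``.  Segmentation is anchored at the
    onset of the first full night, and at most ``max_periods`` consecutive
    24-h periods are returned; later data are discarded.  Durations given in
    hours refer to the recording's own 24-h clock (``recording.day_s``), so
    compressed synthetic days segment identically to real ones.

    ``override`` (list of explicit ``(night_start_s, night_end_s)`` pairs)
    replaces detection entirely — the escape hatch for manual partitioning.
    """
    rate = recording.rate_hz
    day_samples = int(round(recording.day_s * rate))
    hour_s = recording.day_s / 24.0

    if override is not None:
        nights = [
            (int(round(a * rate)), int(round(b * rate))) for (a, b) in override
        ]
    else:
        ai_values = np.asarray(ai_values, dtype=float)
        smooth_windows = int(round(smooth_h * hour_s / ai_window_s))
        profile = _smooth_profile(ai_values, smooth_windows)
        # Adaptive threshold: between the quiet floor and typical active level.
        lo = np.percentile(profile, 5)
        hi = np.percentile(profile, 90)
        thresh = lo + 0.15 * (hi - lo)
        below = profile < thresh
        nights = []
        win_per_sample = ai_window_s * rate
        for a, b in _runs(below):
            dur_h = (b - a) * ai_window_s / hour_s
            if min_night_h <= dur_h <= max_night_h:
                nights.append(
                    (int(round(a * win_per_sample)), int(round(b * win_per_sample)))
                )

    # First *full* night: not clipped by the start of the recording.
    full_nights = [n for n in nights if n[0] > 0]
    if not full_nights:
        raise ValueError(
            "no full night detected; supply a manual day/night override file"
        )
    anchor = full_nights[0][0]
    n_periods = min(max_periods, (recording.n_samples - anchor) // day_samples)
    if n_periods < 1:
        raise ValueError("recording does not span a full 24-h period after the first night")

    periods = [
        (anchor + i * day_samples, anchor + (i + 1) * day_samples)
        for i in range(n_periods)
    ]
    day_intervals: list[list[tuple[int, int]]] = []
    for p_a, p_b in periods:
        cuts = [(max(a, p_a), min(b, p_b)) for (a, b) in nights]
        cuts = sorted((a, b) for (a, b) in cuts if b > a)
        days: list[tuple[int, int]] = []
        pos = p_a
        for a, b in cuts:
            if a > pos:
                days.append((pos, a))
            pos = max(pos, b)
        if pos < p_b:
            days.append((pos, p_b))
        day_intervals.append(days)
    return DaySegmentation(periods=periods, nights=nights, day_intervals=day_intervals)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end) runs of True in a boolean array."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return []
    diff = np.diff(m.astype(int))
    starts = list(np.flatnonzero(diff == 1) + 1)
    ends = list(np.flatnonzero(diff == -1) + 1)
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        ends.append(len(m))
    return list(zip(starts, ends))


# ---------------------------------------------------------------------------
# I/O: CSV + JSON side-car, generic column-mapped reader, manual override file


def write_recording_csv(recording: AccelRecording, path: str | Path) -> None:
    """Write a recording as CSV (timestamp_s, ax, ay, az) with a .meta.json side-car."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "timestamp_s": recording.times(),
            "ax": recording.samples[:, 0],
            "ay": recording.samples[:, 1],
            "az": recording.samples[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")
    meta = {
        "site": recording.site,
        "rate_hz": recording.rate_hz,
        "start_s": recording.start_s,
        "day_s": recording.day_s,
        **{k: v for k, v in recording.meta.items() if _json_safe(v)},
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def read_recording_csv(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    rate_hz: float | None = None,
    site: str | None = None,
) -> AccelRecording:
    """Read a recording CSV; uses the side-car metadata when present.

    ``column_map`` maps canonical names (timestamp_s, ax, ay, az) to the
    actual column names, for generic third-party exports.
    """
    path = Path(path)
    cmap = {"timestamp_s": "timestamp_s", "ax": "ax", "ay": "ay", "az": "az"}
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path)
    meta_path = Path(str(path) + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    t = df[cmap["timestamp_s"]].to_numpy(dtype=float)
    if rate_hz is None:
        rate_hz = meta.get("rate_hz")
    if rate_hz is None:
        dt = np.diff(t)
        rate_hz = 1.0 / np.median(dt)
    # Uniform sampling check: gaps are flagged, never silently interpolated.
    if len(t) > 1:
        dt = np.diff(t)
        gaps = int(np.sum(np.abs(dt - 1.0 / rate_hz) > 0.5 / rate_hz))
    else:
        gaps = 0
    samples = df[[cmap["ax"], cmap["ay"], cmap["az"]]].to_numpy(dtype=float)
    return AccelRecording(
        samples=samples,
        rate_hz=float(rate_hz),
        site=site or meta.get("site", "ankle"),
        start_s=float(meta.get("start_s", t[0] if len(t) else 0.0)),
        day_s=float(meta.get("day_s", SECONDS_PER_DAY)),
        meta={"n_gap_samples": gaps},
    )


def read_day_override(path: str | Path) -> list[tuple[float, float]]:
    """Read a manual night-boundary file: two columns, night_start_s night_end_s."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        a, b = line.replace(",", " ").split()[:2]
        rows.append((float(a), float(b)))
    return rows
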