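"""Activity-index, spectral, directionality and activity-bout features.

The activity index (AI) summarizes, per 1-s window, how much the filtered
acceleration varies above the calibrated sensor-noise floor:

    AI = sqrt( max(0, mean_axes( var_axis - mean_noise_var )) )

Windows below an inactivity threshold are treated as rest.  Activity bouts
are contiguous supra-threshold runs lasting 4-18 s; they are the unit from
which bout kinematics and, downstream, submovements are extracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .preprocess import AccelRecording, _runs

__all__ = [
    "ActivityIndexSeries",
    "ActivityBout",
    "activity_index",
    "ai_distribution_features",
    "directionality",
    "total_power",
    "extract_bouts",
    "bout_kinematics",
]

#: AI intensity cut-points (low < cut1 <= moderate < cut2 <= high), AI units.
#: Conventions of this package; the published cut-points are not available.
DEFAULT_INTENSITY_CUTS = (0.1, 0.5)
DEFAULT_INACTIVITY_THRESHOLD = 0.02
#: Fixed histogram edges for AI mode/entropy: 0-3 AI units in 0.03 steps.
DEFAULT_AI_BIN_EDGES = np.arange(0.0, 3.0 + 1e-9, 0.03)


@dataclass
class ActivityIndexSeries:
    """Per-1-s-window activity index with an inactivity mask."""

    values: np.ndarray
    window_s: float = 1.0
    inactivity_threshold: float = DEFAULT_INACTIVITY_THRESHOLD
    inactivity_mask: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.inactivity_mask = self.values < self.inactivity_threshold

    @property
    def active_values(self) -> np.ndarray:
        return self.values[~self.inactivity_mask]


@dataclass
class ActivityBout:
    """A contiguous supra-threshold activity run of 4-18 s."""

    start: int  # sample index into the filtered recording
    end: int
    window_start: int  # window index into the AI series
    window_end: int
    duration_s: float
    ai_profile: np.ndarray


def activity_index(
    filtered: AccelRecording,
    noise_var: np.ndarray,
    window_s: float = 1.0,
    inactivity_threshold: float = DEFAULT_INACTIVITY_THRESHOLD,
    sample_indices: np.ndarray | None = None,
) -> ActivityIndexSeries:
    """Activity index per complete window; a trailing partial window is dropped.

    ``sample_indices`` restricts the computation to a subset of samples
    (e.g. concatenated daytime segments); windows are then formed on the
    concatenated stream.
    """
    x = filtered.samples
    if sample_indices is not None:
        x = x[np.asarray(sample_indices, dtype=int)]
    w = int(round(window_s * filtered.rate_hz))
    n_win = x.shape[0] // w
    xw = x[: n_win * w].reshape(n_win, w, 3)
    var = xw.var(axis=1)  # (n_win, 3)
    noise = float(np.mean(np.asarray(noise_var, dtype=float)))
    ai = np.sqrt(np.maximum(0.0, (var - noise).mean(axis=1)))
    return ActivityIndexSeries(
        values=ai, window_s=window_s, inactivity_threshold=inactivity_threshold
    )


def ai_distribution_features(
    ai: ActivityIndexSeries,
    intensity_cuts: tuple[float, float] = DEFAULT_INTENSITY_CUTS,
    bin_edges: np.ndarray = DEFAULT_AI_BIN_EDGES,
) -> dict[str, float]:
    """AI mean/median/mode/entropy (active windows) and %low/%moderate/%high.

    Inactive windows are excluded from mean, median, mode and entropy.  The
    intensity percentages are computed over *all* daytime windows, so they
    sum to 100; the mode is the midpoint of the modal histogram bin and the
    entropy is the natural-log Shannon entropy of the fixed-edge histogram.
    Returns NaN-valued entries when no window is active.
    """
    active = ai.active_values
    out: dict[str, float] = {}
    if active.size == 0:
        for k in ("ai_mean", "ai_median", "ai_mode", "ai_entropy"):
            out[k] = np.nan
    else:
        out["ai_mean"] = float(np.mean(active))
        out["ai_median"] = float(np.median(active))
        clipped = np.clip(active, bin_edges[0], bin_edges[-1] - 1e-12)
        counts, _ = np.histogram(clipped, bins=bin_edges)
        imax = int(np.argmax(counts))
        out["ai_mode"] = float(0.5 * (bin_edges[imax] + bin_edges[imax + 1]))
        p = counts[counts > 0] / counts.sum()
        out["ai_entropy"] = float(-(p * np.log(p)).sum())
    c1, c2 = intensity_cuts
    n = ai.values.size
    if n == 0:
        out["pct_low_ai"] = out["pct_moderate_ai"] = out["pct_high_ai"] = np.nan
    else:
        out["pct_low_ai"] = 100.0 * float(np.mean(ai.values < c1))
        out["pct_moderate_ai"] = 100.0 * float(
            np.mean((ai.values >= c1) & (ai.values < c2))
        )
        out["pct_high_ai"] = 100.0 * float(np.mean(ai.values >= c2))
    return out


def directionality(
    filtered: AccelRecording,
    ai: ActivityIndexSeries,
    intensity_cuts: tuple[float, float] = DEFAULT_INTENSITY_CUTS,
    sample_indices: np.ndarray | None = None,
) -> dict[str, float]:
    """Share of per-window acceleration variance along the first principal
    direction, averaged within each AI intensity class (active windows only).

    Returns percentages keyed ``directionality_{low,moderate,high}_ai``;
    a class with no qualifying window yields NaN.
    """
    x = filtered.samples
    if sample_indices is not None:
        x = x[np.asarray(sample_indices, dtype=int)]
    w = int(round(ai.window_s * filtered.rate_hz))
    n_win = min(x.shape[0] // w, ai.values.size)
    xw = x[: n_win * w].reshape(n_win, w, 3)
    xw = xw - xw.mean(axis=1, keepdims=True)
    cov = np.einsum("nti,ntj->nij", xw, xw) / w
    eig = np.linalg.eigvalsh(cov)  # ascending
    total = eig.sum(axis=1)
    valid = total > 0
    share = np.full(n_win, np.nan)
    share[valid] = 100.0 * eig[valid, -1] / total[valid]

    vals = ai.values[:n_win]
    active = ~ai.inactivity_mask[:n_win]
    c1, c2 = intensity_cuts
    classes = {
        "directionality_low_ai": active & (vals < c1),
        "directionality_moderate_ai": active & (vals >= c1) & (vals < c2),
        "directionality_high_ai": active & (vals >= c2),
    }
    out = {}
    for name, mask in classes.items():
        sel = share[mask & valid]
        out[name] = float(np.mean(sel)) if sel.size else np.nan
    return out


def total_power(
    filtered: AccelRecording,
    band: tuple[float, float] = (0.1, 5.0),
    sample_indices: np.ndarray | None = None,
) -> float:
    """Cumulative Welch-PSD power in the 0.1-5 Hz band, summed over axes."""
    x = filtered.samples
    if sample_indices is not None:
        x = x[np.asarray(sample_indices, dtype=int)]
    if x.shape[0] < 60 * filtered.rate_hz:
        raise ValueError("need at least 60 s of daytime signal for total power")
    nperseg = min(x.shape[0], int(40 * filtered.rate_hz))
    f, psd = signal.welch(x, fs=filtered.rate_hz, nperseg=nperseg, axis=0)
    df = f[1] - f[0]
    mask = (f >= band[0]) & (f <= band[1])
    return float(psd[mask].sum() * df)


def extract_bouts(
    ai: ActivityIndexSeries,
    bout_threshold: float | None = None,
    rate_hz: float = 100.0,
    min_dur_s: float = 4.0,
    max_dur_s: float = 18.0,
    overlong: str = "discard",
) -> list[ActivityBout]:
    """Maximal supra-threshold AI runs kept when 4-18 s long.

    Runs longer than ``max_dur_s`` are discarded by default (strict reading
    of the 4-18 s definition) or truncated with ``overlong="truncate"``.
    ``bout_threshold`` defaults to the series' inactivity threshold.
    """
    if bout_threshold is None:
        bout_threshold = ai.inactivity_threshold
    if overlong not in ("discard", "truncate"):
        raise ValueError("overlong must be 'discard' or 'truncate'")
    w = int(round(ai.window_s * rate_hz))
    bouts: list[ActivityBout] = []
    for a, b in _runs(ai.values >= bout_threshold):
        dur = (b - a) * ai.window_s
        if dur < min_dur_s:
            continue
        if dur > max_dur_s:
            if overlong == "discard":
                continue
            b = a + int(round(max_dur_s / ai.window_s))
            dur = (b - a) * ai.window_s
        bouts.append(
            ActivityBout(
                start=a * w,
                end=b * w,
                window_start=a,
                window_end=b,
                duration_s=dur,
                ai_profile=ai.values[a:b].copy(),
            )
        )
    return bouts


def bout_kinematics(
    bouts: list[ActivityBout],
    filtered: AccelRecording,
    sample_indices: np.ndarray | None = None,
) -> dict[str, float]:
    """Across-bout mean/SD of per-bout peak acceleration and mean jerk.

    Per bout: max ||a(t)|| (m/s^2) and mean ||da/dt|| (m/s^3, central
    differences).  SDs are NaN with fewer than two bouts.
    """
    x = filtered.samples
    if sample_indices is not None:
        x = x[np.asarray(sample_indices, dtype=int)]
    dt = 1.0 / filtered.rate_hz
    peak_acc, mean_jerk = [], []
    for bout in bouts:
        seg = x[bout.start : bout.end]
        if seg.shape[0] < 3:
            continue
        peak_acc.append(float(np.linalg.norm(seg, axis=1).max()))
        jerk = np.gradient(seg, dt, axis=0)
        mean_jerk.append(float(np.linalg.norm(jerk, axis=1).mean()))
    peak_acc_arr = np.asarray(peak_acc)
    mean_jerk_arr = np.asarray(mean_jerk)

    def _stat(arr: np.ndarray, fn) -> float:
        if fn is np.std and arr.size < 2:
            return np.nan
        return float(fn(arr)) if arr.size else np.nan

    return {
        "bout_acceleration_mean": _stat(peak_acc_arr, np.mean),
        "bout_acceleration_sd": _stat(peak_acc_arr, np.std),
        "bout_jerk_mean": _stat(mean_jerk_arr, np.mean),
        "bout_jerk_sd": _stat(mean_jerk_arr, np.std),
    }
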