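"""Submovement decomposition of activity bouts and the wearable feature vector.

Each activity bout's band-passed acceleration is integrated to a 3-D velocity
trace, projected by PCA onto its primary (PC1) and secondary (PC2) movement
directions, and each projected axis is cut at velocity zero crossings into
candidate submovements (SMs) — the elementary velocity pulses of natural
movement.  SMs are grouped by duration (short/long) and direction (PC1/PC2),
and their kinematics (distance, peak velocity, peak acceleration, normalized
jerk, duration) plus shape-basis scores are aggregated into the canonical
85-feature per-subject vector, of which 26 are flagged as key features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.integrate import cumulative_trapezoid

from .activity import ActivityBout

__all__ = [
    "BoutVelocity",
    "Submovement",
    "ShapeBasis",
    "WearableFeatureVector",
    "reconstruct_velocity",
    "movement_plane",
    "segment_submovements",
    "sm_kinematics",
    "extract_bout_submovements",
    "fit_sm_shape_basis",
    "analytic_shape_basis",
    "score_submovements",
    "sm_pc_score_features",
    "sm_kinematic_features",
    "assemble_feature_vector",
    "FEATURE_NAMES",
    "KEY_FEATURES",
    "feature_dictionary",
]

#: Default boundary between short- and long-duration SMs (seconds).
SHORT_LONG_CUTOFF_S = 0.2
#: Minimum peak speed (m/s) and duration (s) for a kept submovement.
MIN_PEAK_VELOCITY = 0.05
MIN_SM_DURATION_S = 0.08


@dataclass
class BoutVelocity:
    """3-D bout velocity with its PCA movement plane and 2-D projection."""

    v3: np.ndarray            # (n, 3) m/s
    rate_hz: float
    plane: np.ndarray         # (2, 3) orthonormal PC1/PC2 directions
    v2: np.ndarray            # (n, 2) projections onto PC1/PC2
    variance_explained: np.ndarray  # (2,) fractions


@dataclass
class Submovement:
    """One segmented 1-D velocity pulse with its kinematic scalars."""

    direction: str            # "pc1" | "pc2"
    v_profile: np.ndarray     # 1-D, sign-flipped so the peak is positive
    rate_hz: float
    duration_s: float = field(init=False)
    duration_group: str = field(init=False)
    distance_m: float = np.nan
    peak_velocity: float = np.nan
    peak_acceleration: float = np.nan
    normalized_jerk: float = np.nan
    pc_scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.duration_s = len(self.v_profile) / self.rate_hz
        self.duration_group = (
            "short" if self.duration_s < SHORT_LONG_CUTOFF_S else "long"
        )


def reconstruct_velocity(
    bout_accel: np.ndarray, rate_hz: float
) -> tuple[np.ndarray, float]:
    """Integrate a bout's (n, 3) band-passed acceleration to velocity.

    Trapezoidal integration per axis followed by a linear detrend so each
    axis starts and ends at exactly zero velocity, removing integration
    drift (the bout starts and ends at rest by construction).
    """
    a = np.asarray(bout_accel, dtype=float)
    dt = 1.0 / rate_hz
    v = cumulative_trapezoid(a, dx=dt, axis=0, initial=0.0)
    n = v.shape[0]
    ramp = np.linspace(0.0, 1.0, n)[:, None]
    v = v - ramp * v[-1][None, :]
    return v, rate_hz


def movement_plane(v3: np.ndarray, rate_hz: float) -> BoutVelocity | None:
    """PCA of the bout velocity: top-two eigenvectors define the movement plane.

    The plane is estimated from the mean-centred velocity covariance, but the
    projection keeps the physical zero (no centring) so downstream
    zero-crossing segmentation sees true rest as zero velocity.  Sign
    convention: each direction vector's largest-magnitude component is
    positive.  Returns None for a rank-0 (all-zero) bout.
    """
    v3 = np.asarray(v3, dtype=float)
    c = v3 - v3.mean(axis=0)
    cov = c.T @ c / max(1, v3.shape[0])
    if not np.any(cov):
        return None
    w, vec = np.linalg.eigh(cov)  # ascending
    order = np.argsort(w)[::-1]
    w = np.maximum(w[order], 0.0)
    vec = vec[:, order]
    plane = vec[:, :2].T.copy()
    for i in range(2):
        j = int(np.argmax(np.abs(plane[i])))
        if plane[i, j] < 0:
            plane[i] = -plane[i]
    v2 = v3 @ plane.T
    total = w.sum()
    return BoutVelocity(
        v3=v3,
        rate_hz=rate_hz,
        plane=plane,
        v2=v2,
        variance_explained=w[:2] / total,
    )


def segment_submovements(
    v1d: np.ndarray,
    rate_hz: float,
    direction: str,
    min_peak: float = MIN_PEAK_VELOCITY,
    min_dur_s: float = MIN_SM_DURATION_S,
    zero_tol: float = 1e-12,
) -> list[Submovement]:
    """Cut a projected 1-D velocity trace into submovements at zero crossings.

    Candidate SMs are maximal constant-sign runs (samples with |v| below
    ``zero_tol`` act as separators); a candidate is kept when its peak speed
    reaches ``min_peak`` and it lasts at least ``min_dur_s``.  Profiles are
    sign-flipped so the peak is positive.
    """
    v = np.asarray(v1d, dtype=float)
    s = np.sign(v)
    s[np.abs(v) <= zero_tol] = 0
    out: list[Submovement] = []
    start = None
    cur = 0
    for i in range(len(s) + 1):
        si = s[i] if i < len(s) else 0
        if si != cur:
            if cur != 0 and start is not None:
                seg = v[start:i] * cur
                if (
                    seg.max() >= min_peak
                    and len(seg) / rate_hz >= min_dur_s
                ):
                    out.append(
                        Submovement(direction=direction, v_profile=seg, rate_hz=rate_hz)
                    )
            start = i if si != 0 else None
            cur = si
    return out


def sm_kinematics(sm: Submovement) -> Submovement:
    """Fill distance, peak velocity/acceleration and normalized jerk in place.

    Normalized jerk is the dimensionless smoothness index

        NJ = sqrt( D^3 / v_peak^2 * int j(t)^2 dt ),

    with jerk from central differences of the profile's acceleration.
    """
    v = sm.v_profile
    if len(v) < 4:
        return sm
    dt = 1.0 / sm.rate_hz
    sm.distance_m = float(np.trapezoid(np.abs(v), dx=dt))
    sm.peak_velocity = float(v.max())
    a = np.gradient(v, dt)
    sm.peak_acceleration = float(np.abs(a).max())
    j = np.gradient(a, dt)
    int_j2 = float(np.trapezoid(j**2, dx=dt))
    sm.normalized_jerk = float(
        np.sqrt(sm.duration_s**3 / sm.peak_velocity**2 * int_j2)
    )
    return sm


def extract_bout_submovements(
    bout: ActivityBout,
    samples: np.ndarray,
    rate_hz: float,
    min_peak: float = MIN_PEAK_VELOCITY,
    min_dur_s: float = MIN_SM_DURATION_S,
) -> list[Submovement]:
    """Full bout pipeline: acceleration -> velocity -> plane -> submovements.

    ``samples`` is the (n, 3) band-passed acceleration stream the bout's
    indices refer to (e.g. concatenated daytime samples).
    """
    seg = samples[bout.start : bout.end]
    v3, rate = reconstruct_velocity(seg, rate_hz)
    bv = movement_plane(v3, rate)
    if bv is None:
        return []
    sms: list[Submovement] = []
    for k, direction in enumerate(("pc1", "pc2")):
        for sm in segment_submovements(
            bv.v2[:, k], rate, direction, min_peak=min_peak, min_dur_s=min_dur_s
        ):
            sms.append(sm_kinematics(sm))
    return sms


# ---------------------------------------------------------------------------
# Shape basis and PC-score features


@dataclass
class ShapeBasis:
    """Orthonormal basis for resampled, unit-peak SM velocity shapes."""

    components: np.ndarray   # (n_components, resample_len)
    mean_curve: np.ndarray   # (resample_len,)
    resample_len: int
    source: str              # "pca" | "analytic"


def _resample_unit_peak(profile: np.ndarray, resample_len: int) -> np.ndarray:
    x_old = np.linspace(0.0, 1.0, len(profile))
    x_new = np.linspace(0.0, 1.0, resample_len)
    curve = np.interp(x_new, x_old, profile)
    peak = np.abs(curve).max()
    return curve / peak if peak > 0 else curve


def _fix_signs(components: np.ndarray) -> np.ndarray:
    comps = components.copy()
    n = comps.shape[1]
    for i in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    # Component 1: put its positive peak in the first half when attainable.
    peak = int(np.argmax(comps[0]))
    if peak >= n // 2 and np.argmax(-comps[0]) < n // 2:
        comps[0] = -comps[0]
    return comps


def analytic_shape_basis(n_components: int = 5, resample_len: int = 50) -> ShapeBasis:
    """Fixed sinusoid fallback basis: 0.5, 1, 1.5, 2 and 2.5 cycles.

    The first function is a single half-wave (the canonical SM shape), the
    second a full cycle peaking in the second half, and the higher ones add
    1.5-2.5 cycles of progressively higher-frequency structure.  Functions
    are orthonormalized (QR) with deterministic signs.
    """
    tau = np.linspace(0.0, 1.0, resample_len)
    cycles = [0.5 * (k + 1) for k in range(n_components)]
    raw = np.stack([np.sin(2.0 * np.pi * c * tau) for c in cycles])
    q, _ = np.linalg.qr(raw.T)
    comps = _fix_signs(q.T[:n_components])
    return ShapeBasis(
        components=comps,
        mean_curve=np.zeros(resample_len),
        resample_len=resample_len,
        source="analytic",
    )


def fit_sm_shape_basis(
    sms: list[Submovement],
    n_components: int = 5,
    resample_len: int = 50,
    min_profiles: int = 50,
) -> ShapeBasis:
    """PCA basis of pooled long-duration SM shapes (resampled, unit peak).

    The basis is intended to be fitted once on the pooled cohort and frozen,
    so scores are comparable across subjects and recording halves.  The PCA
    is uncentred, so component 1 is the canonical single-hump pulse shape
    and higher components add progressively higher-frequency structure.
    With fewer than ``min_profiles`` long SMs the fixed analytic sinusoid
    basis is returned instead.
    """
    profiles = [sm.v_profile for sm in sms if sm.duration_group == "long"]
    if len(profiles) < min_profiles:
        return analytic_shape_basis(n_components, resample_len)
    curves = np.stack([_resample_unit_peak(p, resample_len) for p in profiles])
    _, _, vt = np.linalg.svd(curves, full_matrices=False)
    comps = _fix_signs(vt[:n_components])
    return ShapeBasis(
        components=comps,
        mean_curve=curves.mean(axis=0),
        resample_len=resample_len,
        source="pca",
    )


def score_submovements(sms: list[Submovement], basis: ShapeBasis) -> None:
    """Project each SM's resampled unit-peak shape onto the basis (in place)."""
    for sm in sms:
        curve = _resample_unit_peak(sm.v_profile, basis.resample_len)
        sm.pc_scores = basis.components @ curve


def sm_pc_score_features(sms: list[Submovement]) -> dict[str, float]:
    """Mean |score|, SD and kurtosis of PC1-5 scores of long SMs, per direction.

    5 components x 2 directions x 3 statistics = 30 features.  Kurtosis uses
    the non-excess (Pearson) convention, so a normal sample is near 3; it is
    NaN with fewer than 4 SMs in a cell, and all statistics are NaN with
    fewer than 2.
    """
    out: dict[str, float] = {}
    for direction in ("pc1", "pc2"):
        scores = np.array(
            [
                sm.pc_scores
                for sm in sms
                if sm.direction == direction
                and sm.duration_group == "long"
                and sm.pc_scores is not None
            ]
        )
        n = len(scores)
        for k in range(5):
            base = f"sm_pc{k + 1}_score_{direction}"
            if n < 2:
                out[f"{base}_absmean"] = np.nan
                out[f"{base}_sd"] = np.nan
                out[f"{base}_kurtosis"] = np.nan
                continue
            s = scores[:, k]
            out[f"{base}_absmean"] = float(np.abs(s).mean())
            out[f"{base}_sd"] = float(s.std())
            out[f"{base}_kurtosis"] = (
                float(sps.kurtosis(s, fisher=False)) if n >= 4 else np.nan
            )
    return out


def sm_kinematic_features(sms: list[Submovement]) -> dict[str, float]:
    """Across-SM mean/SD of each kinematic quantity per (duration, direction).

    5 quantities x 2 duration groups x 2 directions x 2 statistics = 40
    features; a cell with fewer than 2 SMs yields NaN.
    """
    quantities = {
        "distance": "distance_m",
        "velocity": "peak_velocity",
        "acceleration": "peak_acceleration",
        "jerk": "normalized_jerk",
        "duration": "duration_s",
    }
    out: dict[str, float] = {}
    for qname, attr in quantities.items():
        for dur in ("short", "long"):
            for direction in ("pc1", "pc2"):
                vals = np.array(
                    [
                        getattr(sm, attr)
                        for sm in sms
                        if sm.duration_group == dur
                        and sm.direction == direction
                        and np.isfinite(getattr(sm, attr))
                    ]
                )
                base = f"sm_{qname}_{dur}_{direction}"
                if vals.size < 2:
                    out[f"{base}_mean"] = np.nan
                    out[f"{base}_sd"] = np.nan
                else:
                    out[f"{base}_mean"] = float(vals.mean())
                    out[f"{base}_sd"] = float(vals.std())
    return out


# ---------------------------------------------------------------------------
# Canonical 85-feature schema

_AI_NAMES = [
    "ai_mean",
    "ai_median",
    "ai_mode",
    "ai_entropy",
    "pct_low_ai",
    "pct_moderate_ai",
    "pct_high_ai",
    "directionality_low_ai",
    "directionality_moderate_ai",
    "directionality_high_ai",
]
_SPECTRAL_NAMES = ["total_power"]
_BOUT_NAMES = [
    "bout_acceleration_mean",
    "bout_acceleration_sd",
    "bout_jerk_mean",
    "bout_jerk_sd",
]
_SM_KIN_NAMES = [
    f"sm_{q}_{dur}_{direction}_{stat}"
    for q in ("distance", "velocity", "acceleration", "jerk", "duration")
    for dur in ("short", "long")
    for direction in ("pc1", "pc2")
    for stat in ("mean", "sd")
]
_SM_PC_NAMES = [
    f"sm_pc{k}_score_{direction}_{stat}"
    for k in range(1, 6)
    for direction in ("pc1", "pc2")
    for stat in ("absmean", "sd", "kurtosis")
]

#: The canonical wearable feature schema, in order (85 names).
FEATURE_NAMES: list[str] = (
    _AI_NAMES + _SPECTRAL_NAMES + _BOUT_NAMES + _SM_KIN_NAMES + _SM_PC_NAMES
)

#: The 26 key features preselected for single-feature analysis:
#: AI mean, AI entropy, and all SM distance/velocity/acceleration aggregates.
KEY_FEATURES: frozenset[str] = frozenset(
    ["ai_mean", "ai_entropy"]
    + [n for n in _SM_KIN_NAMES if n.split("_")[1] in ("distance", "velocity", "acceleration")]
)

assert len(FEATURE_NAMES) == 85
assert len(KEY_FEATURES) == 26


@dataclass
class WearableFeatureVector:
    """The 85-feature wearable vector for one subject x site x period set."""

    values: dict[str, float]
    n_bouts: int = 0
    n_submovements: int = 0
    subject_id: str = ""
    site: str = "ankle"
    period: str = "all"

    def __post_init__(self) -> None:
        missing = [n for n in FEATURE_NAMES if n not in self.values]
        extra = [n for n in self.values if n not in FEATURE_NAMES]
        if missing or extra:
            raise ValueError(
                f"feature vector mismatch: missing {missing[:3]}..., extra {extra[:3]}..."
            )

    def as_series(self) -> pd.Series:
        return pd.Series({n: self.values[n] for n in FEATURE_NAMES})

    def key_values(self) -> dict[str, float]:
        return {n: self.values[n] for n in FEATURE_NAMES if n in KEY_FEATURES}


def assemble_feature_vector(
    ai_features: dict[str, float] | None = None,
    directionality_features: dict[str, float] | None = None,
    spectral_features: dict[str, float] | None = None,
    bout_features: dict[str, float] | None = None,
    sm_kin_features: dict[str, float] | None = None,
    sm_pc_features: dict[str, float] | None = None,
    n_bouts: int = 0,
    n_submovements: int = 0,
    subject_id: str = "",
    site: str = "ankle",
    period: str = "all",
) -> WearableFeatureVector:
    """Merge the feature blocks into the canonical 85-entry vector.

    Absent blocks contribute NaN entries; the vector is always emitted with
    all 85 names present.
    """
    values = {n: np.nan for n in FEATURE_NAMES}
    for block in (
        ai_features,
        directionality_features,
        spectral_features,
        bout_features,
        sm_kin_features,
        sm_pc_features,
    ):
        if block:
            for k, v in block.items():
                if k not in values:
                    raise KeyError(f"unknown feature {k!r}")
                values[k] = float(v)
    return WearableFeatureVector(
        values=values,
        n_bouts=n_bouts,
        n_submovements=n_submovements,
        subject_id=subject_id,
        site=site,
        period=period,
    )


def feature_dictionary() -> pd.DataFrame:
    """Name, block, units and key flag for every canonical wearable feature."""
    rows = []
    units = {
        "distance": "m",
        "velocity": "m/s",
        "acceleration": "m/s^2",
        "jerk": "dimensionless",
        "duration": "s",
    }
    for name in FEATURE_NAMES:
        if name in _AI_NAMES:
            block, unit = "activity_index", "%" if name.startswith("pct") or name.startswith("directionality") else "AI units"
        elif name in _SPECTRAL_NAMES:
            block, unit = "spectral", "(m/s^2)^2"
        elif name in _BOUT_NAMES:
            block, unit = "activity_bout", "m/s^2" if "acceleration" in name else "m/s^3"
        elif name in _SM_KIN_NAMES:
            block, unit = "submovement", units[name.split("_")[1]]
        else:
            block, unit = "sm_shape_score", "dimensionless"
        rows.append(
            {
                "feature": name,
                "block": block,
                "units": unit,
                "key": name in KEY_FEATURES,
            }
        )
    return pd.DataFrame(rows)
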