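"""End-to-end cohort runs: synthesize -> preprocess -> features -> models -> stats.

A :class:`RunConfig` freezes every knob of a run; its hash is stamped into
the output manifest so any artifact can be traced to the exact
configuration.  The default study layout mirrors a medium cross-sectional
cohort (controls, preataxic carriers and ataxic participants, six 24-h
wearable periods, eight mouse sessions); the synthetic 24-h periods are
time-compressed so a full cohort runs on a laptop.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import submovements as smv
from .cohort import (
    MouseGenParams,
    ScoreGenParams,
    SubjectSpec,
    WearableGenParams,
    generate_clinical_scores,
    generate_mouse_session,
    generate_recording,
    make_subject_specs,
)
from .models import ModelResult, ModelSpec, evaluate_against_scales, fit_loocv
from .mouse import MOUSE_FEATURE_NAMES, median_session_features, session_features
from .stats import run_validity_tables
from .wearable import ExtractionConfig, WearableExtractor

__all__ = ["RunConfig", "CohortResult", "run_pipeline"]

WEARABLE_SCALES = [
    "sara_total", "bars_total", "sara_gait", "bars_gait", "prom_total", "prom_gait",
]
MOUSE_SCALES = [
    "sara_total", "bars_total", "sara_fnf", "bars_fnf", "prom_total", "prom_arm",
]


@dataclass
class RunConfig:
    """Configuration of a full synthetic-cohort analysis run."""

    n_subjects: int = 20
    n_controls: int = 4
    n_preataxic: int = 2
    days: int = 6
    seed: int = 0
    within_subject_sd: float = 0.02
    site: str = "ankle"
    n_mouse_sessions: int = 8
    rounds: int = 8
    targets_per_round: int = 9
    # Compressed synthetic 24-h period (seconds); 86400 = real time.
    day_s: float = 3600.0
    bout_gap_mean_s: float = 30.0
    noise_sd: float = 0.03
    ambient_sd: float = 0.04
    score_noise: bool = True
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)

    def wearable_params(self) -> WearableGenParams:
        return WearableGenParams(
            day_s=self.day_s,
            bout_gap_mean_s=self.bout_gap_mean_s,
            noise_sd=self.noise_sd,
            ambient_sd=self.ambient_sd,
        )

    def score_params(self) -> ScoreGenParams:
        if self.score_noise:
            return ScoreGenParams()
        return ScoreGenParams(
            sara_noise_sd=0.0, bars_noise_sd=0.0, updrs_noise_sd=0.0, prom_noise_sd=0.0
        )

    @classmethod
    def study_default(cls, seed: int = 0) -> "RunConfig":
        """The default synthetic study: n=40 with 8 controls and 4 preataxic."""
        return cls(n_subjects=40, n_controls=8, n_preataxic=4, seed=seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["extraction"]["intensity_cuts"] = list(d["extraction"]["intensity_cuts"])
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class CohortResult:
    """Bundle of everything a cohort run produces."""

    config: RunConfig
    specs: list[SubjectSpec]
    scores: pd.DataFrame
    wearable_features: dict[str, pd.DataFrame]   # "all", "half_a", "half_b"
    mouse_features: dict[str, pd.DataFrame]
    shape_basis: smv.ShapeBasis
    model_bars: ModelResult
    model_prom: ModelResult
    stats_wearable: pd.DataFrame
    stats_mouse: pd.DataFrame
    n_periods: dict[str, int] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> CohortResult:
    """Run the full cohort analysis; optionally persist all tables."""
    specs = make_subject_specs(
        n_subjects=config.n_subjects,
        n_controls=config.n_controls,
        n_preataxic=config.n_preataxic,
        days=config.days,
        seed=config.seed,
        within_subject_sd=config.within_subject_sd,
    )
    wp = config.wearable_params()
    sp = config.score_params()
    mp = MouseGenParams()

    # --- wearable arm: extract per-period intermediates per subject
    extractors: dict[str, WearableExtractor] = {}
    n_periods: dict[str, int] = {}
    for spec in specs:
        rec = generate_recording(spec, site=config.site, params=wp)
        ex = WearableExtractor(rec, config.extraction)
        ex.release_signals()
        extractors[spec.subject_id] = ex
        n_periods[spec.subject_id] = ex.segmentation.n_periods

    # Pooled, frozen shape basis so scores are comparable across subjects.
    pool: list[smv.Submovement] = []
    for ex in extractors.values():
        pool.extend(sm for sm in ex.submovements() if sm.duration_group == "long")
    rng = np.random.default_rng([config.seed, 42])
    if len(pool) > 4000:
        pool = [pool[i] for i in rng.choice(len(pool), 4000, replace=False)]
    basis = smv.fit_sm_shape_basis(pool)

    wearable_features: dict[str, pd.DataFrame] = {}
    for label in ("all", "half_a", "half_b"):
        rows = {}
        for spec in specs:
            ex = extractors[spec.subject_id]
            k = ex.segmentation.n_periods
            if label == "all":
                sel = None
            elif label == "half_a":
                sel = list(range(k // 2))
            else:
                sel = list(range(k // 2, k))
            vec = ex.feature_vector(
                basis, periods=sel, subject_id=spec.subject_id, period_label=label
            )
            rows[spec.subject_id] = vec.as_series()
        wearable_features[label] = pd.DataFrame(rows).T

    # --- clinical scores
    score_rows = {}
    for spec in specs:
        cs = generate_clinical_scores(spec, sp)
        score_rows[spec.subject_id] = {
            "group": spec.group,
            "severity": spec.severity,
            "sara_total": cs.sara_total,
            "bars_total": cs.bars_total,
            "updrs3_total": cs.updrs3_total,
            "prom_total": cs.prom_total,
            **cs.subscores,
        }
    scores = pd.DataFrame(score_rows).T
    for c in scores.columns:
        if c != "group":
            scores[c] = scores[c].astype(float)

    # --- mouse arm
    mouse_features: dict[str, pd.DataFrame] = {k: {} for k in ("all", "half_a", "half_b")}
    for spec in specs:
        per_session = []
        for si in range(config.n_mouse_sessions):
            sess = generate_mouse_session(
                spec,
                rounds=config.rounds,
                targets_per_round=config.targets_per_round,
                params=mp,
                session_index=si,
            )
            per_session.append(session_features(sess))
        mouse_features["all"][spec.subject_id] = median_session_features(per_session, "all")
        mouse_features["half_a"][spec.subject_id] = median_session_features(
            per_session, "first_half"
        )
        mouse_features["half_b"][spec.subject_id] = median_session_features(
            per_session, "second_half"
        )
    mouse_features = {
        k: pd.DataFrame(v).T[MOUSE_FEATURE_NAMES] for k, v in mouse_features.items()
    }

    # --- composite models (wearable features -> clinical targets)
    model_bars = fit_loocv(
        wearable_features["all"], scores["bars_total"],
        ModelSpec(target_name="bars_total", seed=config.seed),
    )
    evaluate_against_scales(model_bars, scores, WEARABLE_SCALES)
    model_prom = fit_loocv(
        wearable_features["all"], scores["prom_total"],
        ModelSpec(target_name="prom_total", seed=config.seed),
    )
    evaluate_against_scales(model_prom, scores, WEARABLE_SCALES)

    # --- statistics tables (BH family per sensor type)
    stats_wearable = run_validity_tables(
        wearable_features["all"],
        wearable_features["half_a"],
        wearable_features["half_b"],
        scores,
        WEARABLE_SCALES,
        family="wearable",
    )
    stats_mouse = run_validity_tables(
        mouse_features["all"],
        mouse_features["half_a"],
        mouse_features["half_b"],
        scores,
        MOUSE_SCALES,
        family="mouse",
    )

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "n_subjects": len(specs),
        "n_periods": n_periods,
        "n_wearable_features": int(wearable_features["all"].shape[1]),
        "n_mouse_features": int(mouse_features["all"].shape[1]),
        "shape_basis_source": basis.source,
    }
    result = CohortResult(
        config=config,
        specs=specs,
        scores=scores,
        wearable_features=wearable_features,
        mouse_features=mouse_features,
        shape_basis=basis,
        model_bars=model_bars,
        model_prom=model_prom,
        stats_wearable=stats_wearable,
        stats_mouse=stats_mouse,
        n_periods=n_periods,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def write_feature_table_long(
    tables: dict[str, pd.DataFrame], site: str, path: Path
) -> None:
    """Shared long-format feature writer: subject, site, period, feature, value."""
    rows = []
    for period, df in tables.items():
        melted = df.reset_index(names="subject").melt(
            id_vars="subject", var_name="feature", value_name="value"
        )
        melted.insert(1, "site", site)
        melted.insert(2, "period", period)
        rows.append(melted)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def _write_outputs(result: CohortResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    h = result.manifest["config_hash"]
    result.scores.to_csv(out_dir / f"scores_{h}.csv")
    for label, df in result.wearable_features.items():
        df.to_csv(out_dir / f"wearable_features_{label}_{h}.csv")
    for label, df in result.mouse_features.items():
        df.to_csv(out_dir / f"mouse_features_{label}_{h}.csv")
    write_feature_table_long(
        result.wearable_features, result.config.site,
        out_dir / f"wearable_features_long_{h}.csv",
    )
    write_feature_table_long(
        result.mouse_features, "mouse", out_dir / f"mouse_features_long_{h}.csv"
    )
    result.stats_wearable.to_csv(out_dir / f"stats_wearable_{h}.csv")
    result.stats_mouse.to_csv(out_dir / f"stats_mouse_{h}.csv")
    for name, model in (("bars", result.model_bars), ("prom", result.model_prom)):
        doc = {
            "target": model.target_name,
            "oof_predictions": model.oof_predictions.to_dict(),
            "selection_frequency": model.selection_frequency.to_dict(),
            "mean_coefficients": model.mean_coefficients.to_dict(),
            "mean_selected": model.mean_selected,
            "evaluation": result_eval_dict(model),
        }
        (out_dir / f"model_{name}_{h}.json").write_text(json.dumps(doc, indent=1))
        model.mean_coefficients.to_csv(out_dir / f"model_{name}_coefficients_{h}.csv")
    (out_dir / f"manifest_{h}.json").write_text(json.dumps(result.manifest, indent=1))


def result_eval_dict(model: ModelResult) -> dict:
    if model.evaluation is None:
        return {}
    return {
        scale: {k: (None if pd.isna(v) else v) for k, v in row.items()}
        for scale, row in model.evaluation.to_dict(orient="index").items()
    }
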