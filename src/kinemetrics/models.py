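"""Composite severity models: L1-regularized regression with LOOCV.

All 85 wearable features feed a lasso model trained to estimate a clinical
target (BARS total for ataxia severity, PROM-Ataxia for self-reported
function).  Generalization is estimated with leave-one-out cross-validation:
for every held-out subject the imputation medians, z-scoring parameters and
the regularization strength (inner 5-fold CV, one-standard-error rule) are
fitted on the remaining subjects only, so no information leaks from the
held-out subject.  Feature-selection stability is summarized as the fraction
of outer folds in which each feature received a non-zero coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold

from .stats import pearson_ci

__all__ = ["ModelSpec", "ModelResult", "fit_loocv", "evaluate_against_scales"]

_COEF_TOL = 1e-10


@dataclass
class ModelSpec:
    target_name: str
    feature_set: list[str] | None = None  # None = all columns of X
    lambda_grid: np.ndarray | None = None  # None = sd(y_train) * logspace grid
    standardize: bool = True
    inner_cv_folds: int = 5
    seed: int = 0


@dataclass
class ModelResult:
    target_name: str
    oof_predictions: pd.Series
    per_fold_selected: list[list[str]]
    selection_frequency: pd.Series
    mean_coefficients: pd.Series
    chosen_lambdas: np.ndarray
    evaluation: pd.DataFrame | None = None

    @property
    def mean_selected(self) -> float:
        return float(np.mean([len(s) for s in self.per_fold_selected]))


def _default_grid(y: np.ndarray) -> np.ndarray:
    return float(np.std(y)) * np.logspace(-2.5, 0.0, 21)


def _prepare(
    X: np.ndarray, medians: np.ndarray, mu: np.ndarray, sd: np.ndarray
) -> np.ndarray:
    X = np.where(np.isnan(X), medians[None, :], X)
    return (X - mu[None, :]) / sd[None, :]


def fit_loocv(X: pd.DataFrame, y: pd.Series, spec: ModelSpec) -> ModelResult:
    """Leave-one-out lasso with per-fold imputation, z-scoring and lambda choice.

    Missing feature values are imputed with the training fold's median; each
    feature is then z-scored with training-fold parameters.  The inner
    k-fold CV picks the largest lambda whose mean squared error is within
    one standard error of the minimum, then the model is refitted on the
    whole training fold at that lambda and the held-out subject's prediction
    is recorded.  Coefficients are reported on the standardized scale.
    """
    cols = spec.feature_set or list(X.columns)
    Xm = X[cols].to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    n, p = Xm.shape
    if n < 10:
        raise ValueError(f"need >= 10 subjects for LOOCV; have {n}")
    if np.std(yv) == 0:
        raise ValueError("constant target")
    all_missing = np.isnan(Xm).all(axis=0)
    if all_missing.any():
        raise ValueError(
            f"all-missing feature columns: {list(np.array(cols)[all_missing])}"
        )

    oof = np.empty(n)
    chosen = np.empty(n)
    selected: list[list[str]] = []
    coefs = np.zeros((n, p))
    for i in range(n):
        tr = np.delete(np.arange(n), i)
        Xt, yt = Xm[tr], yv[tr]
        medians = np.nanmedian(Xt, axis=0)
        Xt_f = np.where(np.isnan(Xt), medians[None, :], Xt)
        mu = Xt_f.mean(axis=0)
        sd = Xt_f.std(axis=0)
        sd[sd == 0] = 1.0
        Zt = (Xt_f - mu[None, :]) / sd[None, :]
        grid = spec.lambda_grid if spec.lambda_grid is not None else _default_grid(yt)
        lam = _one_se_lambda(Zt, yt, grid, spec.inner_cv_folds, spec.seed)
        model = Lasso(alpha=lam, max_iter=50000)
        model.fit(Zt, yt)
        zi = _prepare(Xm[i : i + 1], medians, mu, sd)
        oof[i] = model.predict(zi)[0]
        chosen[i] = lam
        mask = np.abs(model.coef_) > _COEF_TOL
        selected.append([c for c, m in zip(cols, mask) if m])
        coefs[i] = model.coef_

    sel_freq = pd.Series(
        [np.mean([c in s for s in selected]) for c in cols], index=cols
    )
    return ModelResult(
        target_name=spec.target_name,
        oof_predictions=pd.Series(oof, index=X.index, name=spec.target_name),
        per_fold_selected=selected,
        selection_frequency=sel_freq,
        mean_coefficients=pd.Series(coefs.mean(axis=0), index=cols),
        chosen_lambdas=chosen,
    )


def _one_se_lambda(
    Z: np.ndarray, y: np.ndarray, grid: np.ndarray, k: int, seed: int
) -> float:
    """Largest lambda with CV MSE within one SE of the minimum."""
    grid = np.sort(np.asarray(grid, dtype=float))
    kf = KFold(n_splits=min(k, len(y)), shuffle=True, random_state=seed)
    mses = np.zeros((kf.get_n_splits(), len(grid)))
    for f, (tr, te) in enumerate(kf.split(Z)):
        for j, lam in enumerate(grid):
            m = Lasso(alpha=lam, max_iter=50000)
            m.fit(Z[tr], y[tr])
            mses[f, j] = np.mean((y[te] - m.predict(Z[te])) ** 2)
    mean = mses.mean(axis=0)
    se = mses.std(axis=0, ddof=1) / np.sqrt(mses.shape[0])
    jmin = int(np.argmin(mean))
    ok = np.flatnonzero(mean <= mean[jmin] + se[jmin])
    return float(grid[ok.max()])


def evaluate_against_scales(
    result: ModelResult,
    scores: pd.DataFrame,
    scale_names: list[str],
    restrict: str = "ataxia_only",
) -> pd.DataFrame:
    """Pearson r (+ Fisher 95% CI) of out-of-fold predictions vs each scale.

    ``restrict="ataxia_only"`` drops control subjects before correlating, to
    avoid group-separation inflating the coefficients; preataxic mutation
    carriers are part of the ataxia group.
    """
    if restrict not in ("ataxia_only", "all"):
        raise ValueError(f"unknown restriction {restrict!r}")
    idx = scores.index.intersection(result.oof_predictions.index)
    sub = scores.loc[idx]
    if restrict == "ataxia_only":
        sub = sub[sub["group"] != "control"]
    if len(sub) < 4:
        raise ValueError(f"only {len(sub)} subjects after restriction")
    preds = result.oof_predictions.loc[sub.index]
    rows = []
    for name in scale_names:
        res = pearson_ci(preds.to_numpy(), sub[name].to_numpy(dtype=float))
        rows.append({"scale": name, **res})
    table = pd.DataFrame(rows).set_index("scale")
    result.evaluation = table
    return table
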