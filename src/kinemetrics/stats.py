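"""Reliability and validity statistics harness.

Correlations with Fisher confidence intervals, split-half test-retest ICC
(two-way mixed, single measure), Mann-Whitney group contrasts with Cohen's d,
Benjamini-Hochberg multiple-testing correction, and the table builder that
applies them feature-wise to a cohort (one correction family per sensor
type).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "pearson_ci",
    "icc_single",
    "group_contrast",
    "benjamini_hochberg",
    "run_validity_tables",
]


def pearson_ci(x: np.ndarray, y: np.ndarray) -> dict:
    """Pearson r with Fisher-z 95% CI and two-sided p.

    Pairs with non-finite entries are dropped.  Zero variance in either
    variable leaves the correlation undefined: NaN results, ``valid=False``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValueError(f"need >= 4 finite pairs; have {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        return {"r": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                "n": n, "valid": False}
    r, p = sps.pearsonr(x, y)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    hw = 1.96 / np.sqrt(n - 3)
    return {
        "r": float(r),
        "ci_low": float(np.tanh(z - hw)),
        "ci_high": float(np.tanh(z + hw)),
        "p": float(p),
        "n": n,
        "valid": True,
    }


def icc_single(
    half_a: np.ndarray, half_b: np.ndarray, form: str = "consistency"
) -> float:
    """Single-measure ICC from a two-way mixed-effects model on paired halves.

    ``consistency`` is ICC(3,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E);
    ``agreement`` additionally penalizes a systematic shift between halves
    via the column mean square.  NaN pairs are dropped; zero between-subject
    variance leaves the ICC undefined (NaN).
    """
    if form not in ("consistency", "agreement"):
        raise ValueError(f"unknown ICC form {form!r}")
    a = np.asarray(half_a, dtype=float)
    b = np.asarray(half_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("halves must be paired")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    n = len(a)
    if n < 5:
        raise ValueError(f"need >= 5 paired subjects; have {n}")
    data = np.column_stack([a, b])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_rows <= 0:
        return np.nan
    if form == "consistency":
        denom = ms_rows + (k - 1) * ms_err
    else:
        denom = ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
    return float((ms_rows - ms_err) / denom) if denom > 0 else np.nan


def group_contrast(ataxia: np.ndarray, control: np.ndarray) -> dict:
    """Mann-Whitney U (exact for small samples) and Cohen's d.

    d uses the pooled SD with (n-1) weights.  Fully tied data yield p = 1,
    d = 0.
    """
    x = np.asarray(ataxia, dtype=float)
    y = np.asarray(control, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both groups need >= 2 finite values")
    if np.ptp(np.concatenate([x, y])) == 0:
        return {"u": len(x) * len(y) / 2.0, "p": 1.0, "cohen_d": 0.0,
                "n1": len(x), "n2": len(y)}
    method = "exact" if len(x) + len(y) < 20 else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    sp = np.sqrt(
        ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1))
        / (len(x) + len(y) - 2)
    )
    d = (x.mean() - y.mean()) / sp if sp > 0 else 0.0
    return {
        "u": float(res.statistic),
        "p": float(res.pvalue),
        "cohen_d": float(d),
        "n1": len(x),
        "n2": len(y),
    }


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Step-up BH adjusted p-values, order-preserving, capped at 1.

    NaN entries are passed through unadjusted and do not count toward the
    family size.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        if np.any((p[ok] < 0) | (p[ok] > 1)):
            raise ValueError("p-values must lie in [0, 1]")
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Cohort-level validity/reliability tables


def run_validity_tables(
    features: pd.DataFrame,
    half_a: pd.DataFrame,
    half_b: pd.DataFrame,
    scores: pd.DataFrame,
    scale_names: list[str],
    family: str,
    icc_form: str = "consistency",
) -> pd.DataFrame:
    """Per-feature validity and reliability table for one sensor family.

    For each feature column: Pearson r (+p) versus each requested clinical
    scale over ataxia participants only, split-half test-retest ICC, and the
    ataxia-versus-control Mann-Whitney contrast with Cohen's d.  BH
    correction is applied within this family (one family per sensor type),
    separately per scale and for the group contrast.
    """
    idx = features.index
    scores = scores.loc[idx]
    ataxia_mask = (scores["group"] != "control").to_numpy()
    rows = []
    for feat in features.columns:
        v = features[feat].to_numpy(dtype=float)
        row: dict = {"feature": feat, "family": family}
        for scale in scale_names:
            s = scores[scale].to_numpy(dtype=float)
            try:
                res = pearson_ci(v[ataxia_mask], s[ataxia_mask])
            except ValueError:
                res = {"r": np.nan, "p": np.nan, "n": 0}
            row[f"r_{scale}"] = res["r"]
            row[f"p_{scale}"] = res["p"]
        try:
            row["icc"] = icc_single(
                half_a[feat].to_numpy(dtype=float),
                half_b[feat].to_numpy(dtype=float),
                form=icc_form,
            )
        except ValueError:
            row["icc"] = np.nan
        try:
            gc = group_contrast(v[ataxia_mask], v[~ataxia_mask])
            row["u"] = gc["u"]
            row["p_group"] = gc["p"]
            row["cohen_d"] = gc["cohen_d"]
        except ValueError:
            row["u"] = row["p_group"] = row["cohen_d"] = np.nan
        row["n"] = int(np.isfinite(v).sum())
        rows.append(row)
    table = pd.DataFrame(rows).set_index("feature")
    for scale in scale_names:
        table[f"p_bh_{scale}"] = benjamini_hochberg(table[f"p_{scale}"].to_numpy())
    table["p_bh_group"] = benjamini_hochberg(table["p_group"].to_numpy())
    return table
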