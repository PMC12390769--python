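"""Glioma-cohort compensation analysis.

ROI grey-matter-volume (GMV) patient-vs-control comparisons with BH-FDR,
partial Pearson correlations between GMV and linguistic scores, and the
summary-statistic demographic tests used for cohort tables (pooled-variance
two-sample t from printed moments; Pearson chi-square without continuity
correction for 2x2 sex tables).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ROI_LABELS
from .differential_expression import bh_fdr

LINGUISTIC_SCORES = ("AQ", "spontaneous_speech", "comprehension",
                     "repetition", "naming")


def validate_cohort(cohort: pd.DataFrame) -> list[str]:
    """Internal-consistency checks; returns warning strings (never raises
    for reproducibility of published summary tables)."""
    findings = []
    if "group" not in cohort.columns:
        findings.append("missing 'group' column")
        return findings
    sizes = cohort["group"].value_counts()
    for g in ("patient", "control"):
        if sizes.get(g, 0) < 2:
            findings.append(f"group {g!r} has fewer than 2 subjects")
    gmv_cols = [c for c in cohort.columns if c.startswith("gmv_")]
    if not gmv_cols:
        findings.append("no gmv_<ROI> columns present")
    for c in gmv_cols:
        if not np.isfinite(cohort[c].to_numpy(dtype=float)).all():
            findings.append(f"non-finite GMV values in {c}")
    for f in findings:
        warnings.warn(f, stacklevel=2)
    return findings


def roi_gmv_compare(cohort: pd.DataFrame, use_welch: bool = False
                    ) -> pd.DataFrame:
    """Per-ROI two-sample t of patient vs control GMV with BH-FDR.

    Default is the pooled-variance Student t; direction is the sign of
    (patient mean - control mean).
    """
    gmv_cols = [c for c in cohort.columns if c.startswith("gmv_")]
    if not gmv_cols:
        raise ValueError("cohort table has no gmv_<ROI> columns")
    pat = cohort[cohort["group"] == "patient"]
    ctl = cohort[cohort["group"] == "control"]
    if len(pat) < 2 or len(ctl) < 2:
        raise ValueError("both groups need at least 2 subjects")
    t_vals, p_vals, direction = [], [], []
    for c in gmv_cols:
        a = pat[c].to_numpy(dtype=float)
        b = ctl[c].to_numpy(dtype=float)
        res = stats.ttest_ind(a, b, equal_var=not use_welch)
        t_vals.append(float(res.statistic))
        p_vals.append(float(res.pvalue))
        direction.append(int(np.sign(a.mean() - b.mean())))
    q = bh_fdr(p_vals)
    return pd.DataFrame({
        "roi": [c[len("gmv_"):] for c in gmv_cols],
        "t": t_vals, "p": p_vals, "q": q, "direction": direction,
    })


def partial_correlation(x: np.ndarray, y: np.ndarray,
                        covariates: np.ndarray | None = None
                        ) -> tuple[float, float, int]:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualised on the covariates (with intercept) by
    least squares; the correlation of the residuals is tested with
    t distribution on n - 2 - k degrees of freedom.  Returns (r, p, n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must share length")
    if covariates is None or (hasattr(covariates, "size")
                              and np.asarray(covariates).size == 0):
        Z = np.ones((n, 1))
        k = 0
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise ValueError("covariates must have one row per observation")
        Z = np.hstack([np.ones((n, 1)), cov])
        k = cov.shape[1]
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            raise ValueError("covariates are rank-deficient")
    if n <= k + 2:
        raise ValueError("need n > n_covariates + 2")
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("zero residual variance; partial correlation undefined")
    r = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    df = n - 2 - k
    r_c = min(max(r, -1.0), 1.0)
    if abs(r_c) == 1.0:
        p = 0.0
    else:
        t = r_c * np.sqrt(df / (1.0 - r_c ** 2))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p, n


def gmv_score_correlations(cohort: pd.DataFrame,
                           rois: list[str] | None = None,
                           scores: tuple[str, ...] = LINGUISTIC_SCORES,
                           covariates: tuple[str, ...] = ("age", "sex"),
                           group: str = "patient") -> pd.DataFrame:
    """Partial correlations between ROI GMV and linguistic scores.

    Computed within one group (default: patients), controlling for the given
    covariate columns (sex is coded 0/1).  Rows with missing values in any
    used column are dropped per (roi, score) pair.
    """
    sub = cohort[cohort["group"] == group]
    rois = rois or [l for l in ROI_LABELS if f"gmv_{l}" in cohort.columns]
    rows = []
    for roi in rois:
        for score in scores:
            if score not in sub.columns:
                continue
            cols = [f"gmv_{roi}", score, *[c for c in covariates
                                           if c in sub.columns]]
            block = sub[cols].dropna()
            if len(block) <= len(covariates) + 3:
                continue
            cov = None
            used = [c for c in covariates if c in block.columns]
            if used:
                enc = block[used].copy()
                if "sex" in enc.columns:
                    enc["sex"] = (enc["sex"] == "M").astype(float)
                cov = enc.to_numpy(dtype=float)
            r, p, n = partial_correlation(
                block[f"gmv_{roi}"].to_numpy(dtype=float),
                block[score].to_numpy(dtype=float), cov)
            rows.append({"roi": roi, "score_name": score, "r_partial": r,
                         "p": p, "n": n, "covariates": ",".join(used)})
    return pd.DataFrame(rows)


def two_sample_t_from_summary(mean1: float, sd1: float, n1: int,
                              mean2: float, sd2: float, n2: int
                              ) -> tuple[float, float]:
    """Pooled-variance Student t from printed summary moments."""
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                     equal_var=True)
    return float(res.statistic), float(res.pvalue)


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) for a 2x2 table
    [[a, b], [c, d]]."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("all marginals must be positive")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)
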