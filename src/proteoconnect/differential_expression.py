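"""Pairwise region differential expression and DEP counting.

A differentially expressed protein (DEP) between two ROI groups satisfies
p < .05 and |avg_log2FC| > .1 (strict inequalities), where avg_log2FC is
the difference of group means on the log2 scale.  The default test is the
two-sided Wilcoxon rank-sum, computed exactly (no continuity correction)
whenever both groups have at most ``EXACT_MAX`` samples and the data are
tie-free; a Welch t option is available.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    N_REGIONS,
    ProteinMatrix,
    group_labels,
    split_roi_label,
    validate_sample_meta,
)
from .preprocess import DEFAULT_MIN_DONORS

DEP_P_THRESHOLD = 0.05
DEP_FC_THRESHOLD = 0.1
HIGHLIGHT_FC_THRESHOLD = 5.0
EXACT_MAX = 10


def bh_fdr(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving, q >= p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


@lru_cache(maxsize=64)
def _exact_u_distribution(n1: int, n2: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Exact null pmf of the Mann-Whitney U statistic (tie-free).

    Returns (cdf, sf, total) as counts: cdf[u] = #{arrangements: U <= u},
    sf[u] = #{arrangements: U >= u}, total = C(n1+n2, n1).
    """
    # Gaussian-binomial recurrence: c(m1, m2, u) = c(m1-1, m2, u-m2)
    # + c(m1, m2-1, u), with c(0, m2, 0) = c(m1, 0, 0) = 1
    table: list[list[np.ndarray]] = [
        [np.array([1.0])] * (n2 + 1) for _ in range(n1 + 1)]
    for m1 in range(1, n1 + 1):
        for m2 in range(1, n2 + 1):
            arr = np.zeros(m1 * m2 + 1)
            left = table[m1 - 1][m2]
            arr[m2:m2 + left.size] += left
            down = table[m1][m2 - 1]
            arr[:down.size] += down
            table[m1][m2] = arr
    pmf = table[n1][n2]
    total = float(pmf.sum())
    cdf = np.cumsum(pmf)
    sf = np.cumsum(pmf[::-1])[::-1]
    return cdf, sf, total


def _exact_two_sided_p(u: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """Two-sided exact p: P(U <= u_min) + P(U >= n1*n2 - u_min)."""
    cdf, sf, total = _exact_u_distribution(n1, n2)
    u = np.asarray(u, dtype=int)
    u_min = np.minimum(u, n1 * n2 - u)
    p = (cdf[u_min] + sf[n1 * n2 - u_min]) / total
    return np.minimum(p, 1.0)


def rank_sum_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorised two-sided Wilcoxon rank-sum p over rows.

    NaN entries (undetected donors) are ignored per row.  Rows with no ties
    and both group sizes <= EXACT_MAX use the exact null distribution; other
    rows fall back to the normal approximation with tie correction.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    na = a.shape[1]
    combined = np.hstack([a, b])
    obs = ~np.isnan(combined)
    # NaNs replaced by +inf rank last and leave the finite ranks intact
    filled = np.where(obs, combined, np.inf)
    ranks = stats.rankdata(filled, axis=1)
    n1 = obs[:, :na].sum(axis=1)
    n2 = obs[:, na:].sum(axis=1)
    r1 = np.where(obs[:, :na], ranks[:, :na], 0.0).sum(axis=1)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    srt = np.sort(combined, axis=1)  # NaNs sort last; diff with NaN is NaN
    has_ties = (np.diff(srt, axis=1) == 0).any(axis=1)

    p = np.full(a.shape[0], np.nan)
    sizes = np.stack([n1, n2], axis=1)
    for n1v, n2v in np.unique(sizes, axis=0):
        rows = np.flatnonzero((n1 == n1v) & (n2 == n2v))
        if n1v == 0 or n2v == 0:
            continue
        exact = rows[~has_ties[rows]] if max(n1v, n2v) <= EXACT_MAX else \
            np.array([], dtype=int)
        if exact.size:
            p[exact] = _exact_two_sided_p(u1[exact], int(n1v), int(n2v))
        rest = np.setdiff1d(rows, exact, assume_unique=True)
        for i in rest:
            av = a[i][~np.isnan(a[i])]
            bv = b[i][~np.isnan(b[i])]
            res = stats.mannwhitneyu(av, bv, alternative="two-sided",
                                     method="asymptotic")
            p[i] = float(res.pvalue)
    return p


def enumerate_rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Brute-force two-sided rank-sum p by exhaustive enumeration.

    Counts the fraction of all C(n1+n2, n1) rank assignments whose rank-sum
    deviates from its null mean by at least the observed amount.  Intended
    as an independent oracle for small fixtures (tie-free data).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    combined = np.concatenate([a, b])
    if len(np.unique(combined)) != len(combined):
        raise ValueError("enumeration oracle requires tie-free data")
    ranks = stats.rankdata(combined)
    w_obs = ranks[:n1].sum()
    mean_w = n1 * (n1 + n2 + 1) / 2.0
    dev = abs(w_obs - mean_w)
    count = 0
    total = 0
    for comb in itertools.combinations(range(n1 + n2), n1):
        w = sum(sorted(ranks)[i] for i in comb)
        total += 1
        if abs(w - mean_w) >= dev - 1e-12:
            count += 1
    return count / total


@dataclass
class DEPCountMatrix:
    """Symmetric DEP counts for every unordered ROI pair."""

    counts: pd.DataFrame
    pair_class: pd.DataFrame  # 'left' | 'right' | 'cross' per pair

    def __post_init__(self) -> None:
        c = self.counts.to_numpy(dtype=float)
        if not np.allclose(c, c.T) or np.any(np.diag(c) != 0):
            raise ValueError("DEP counts must be symmetric with zero diagonal")


def _group_columns(m: ProteinMatrix, meta: pd.DataFrame) -> dict[str, list[str]]:
    groups = group_labels(meta)
    return {g: list(groups.index[groups == g]) for g in groups.unique()}


def pairwise_de(m: ProteinMatrix, meta: pd.DataFrame, region_a: str,
                region_b: str, test: str = "wilcoxon",
                min_donors: int = DEFAULT_MIN_DONORS) -> pd.DataFrame:
    """Differential expression between two ROI groups.

    ``region_a``/``region_b`` are ROI labels like ``BA22_L``.  avg_log2FC is
    mean(log2 A) - mean(log2 B) over detected donors.  Proteins with fewer
    than ``min_donors`` detected donors in either group are skipped.  BH-FDR
    is computed across the tested proteins of this comparison.
    """
    if not m.is_log2:
        raise ValueError("differential expression expects the log2 matrix")
    if test not in ("wilcoxon", "t"):
        raise ValueError(f"unknown test {test!r}")
    validate_sample_meta(meta)
    cols = _group_columns(m, meta)
    for r in (region_a, region_b):
        if r not in cols:
            raise ValueError(f"unknown region group {r!r}")
    A = m.values[cols[region_a]].to_numpy(dtype=float)
    B = m.values[cols[region_b]].to_numpy(dtype=float)
    return _pairwise_de_arrays(A, B, m.values.index, test=test,
                               min_donors=min_donors)


def _pairwise_de_arrays(A: np.ndarray, B: np.ndarray, index: pd.Index,
                        test: str, min_donors: int) -> pd.DataFrame:
    obs_a = ~np.isnan(A)
    obs_b = ~np.isnan(B)
    usable = (obs_a.sum(axis=1) >= min_donors) & (obs_b.sum(axis=1) >= min_donors)
    idx_usable = np.flatnonzero(usable)
    if idx_usable.size == 0:
        return pd.DataFrame(columns=["protein_id", "avg_log2FC", "p", "q",
                                     "is_dep", "is_highlighted"])

    A = A[idx_usable]
    B = B[idx_usable]
    fc = np.nanmean(A, axis=1) - np.nanmean(B, axis=1)
    if test == "wilcoxon":
        p = rank_sum_pvalues(A, B)
    else:
        res = stats.ttest_ind(A, B, axis=1, equal_var=False,
                              nan_policy="omit")
        p = np.asarray(res.pvalue)

    q = bh_fdr(p)
    is_dep = (p < DEP_P_THRESHOLD) & (np.abs(fc) > DEP_FC_THRESHOLD)
    return pd.DataFrame({
        "protein_id": index[idx_usable],
        "avg_log2FC": fc,
        "p": p,
        "q": q,
        "is_dep": is_dep,
        "is_highlighted": np.abs(fc) >= HIGHLIGHT_FC_THRESHOLD,
    }).reset_index(drop=True)


def _pair_hemisphere_class(label_a: str, label_b: str) -> str:
    ha = split_roi_label(label_a)[1]
    hb = split_roi_label(label_b)[1]
    if ha == hb:
        return "left" if ha == "L" else "right"
    return "cross"


def dep_count_matrix(m: ProteinMatrix, meta: pd.DataFrame,
                     test: str = "wilcoxon",
                     min_donors: int = DEFAULT_MIN_DONORS,
                     use_q: bool = False) -> DEPCountMatrix:
    """DEP count for all unordered ROI-group pairs (325 pairs for 26 ROIs).

    Counts use the raw-p DEP rule by default; ``use_q`` switches the p
    threshold to the BH-FDR q-value within each comparison.
    """
    if not m.is_log2:
        raise ValueError("differential expression expects the log2 matrix")
    validate_sample_meta(meta)
    groups = group_labels(meta)
    labels = sorted(groups.unique(),
                    key=lambda g: (split_roi_label(g)[1],
                                   _region_order(split_roi_label(g)[0])))
    vals = m.values.to_numpy(dtype=float)
    col_pos = {c: i for i, c in enumerate(m.values.columns)}
    arrays = {g: vals[:, [col_pos[s] for s in groups.index[groups == g]]]
              for g in labels}
    n = len(labels)
    counts = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    classes = pd.DataFrame("", index=labels, columns=labels)
    for a, b in itertools.combinations(labels, 2):
        de = _pairwise_de_arrays(arrays[a], arrays[b], m.values.index,
                                 test=test, min_donors=min_donors)
        if use_q and len(de):
            dep = ((de["q"] < DEP_P_THRESHOLD)
                   & (de["avg_log2FC"].abs() > DEP_FC_THRESHOLD)).sum()
        else:
            dep = int(de["is_dep"].sum()) if len(de) else 0
        counts.loc[a, b] = counts.loc[b, a] = dep
        cls = _pair_hemisphere_class(a, b)
        classes.loc[a, b] = classes.loc[b, a] = cls
    return DEPCountMatrix(counts=counts, pair_class=classes)


def _region_order(region: str) -> int:
    from .datatypes import REGIONS

    try:
        return REGIONS.index(region)
    except ValueError:
        return N_REGIONS
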