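"""Excitation/inhibition expression ratio and hemisphere-asymmetric
FC-E/I correlation analysis.

The E/I ratio per region is the summed linear abundance of excitatory
(AMPA + NMDA subunit) genes divided by the summed abundance of inhibitory
(GABA-A subunit) genes, computed from region-mean intensities.  Left- and
right-hemisphere FC-E/I correlations (13 matched regions each) are compared
with Steiger's Z for two dependent, non-overlapping correlations (Fisher
Delta-Z reported), with an independent-samples Fisher-z fallback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    ProteinMatrix,
    REGIONS,
    group_labels,
    validate_sample_meta,
)
from .gene_sets import EIGeneSets


@dataclass
class EIRecord:
    region: str
    hemisphere: str
    e_sum: float
    i_sum: float
    ei_ratio: float
    n_excitatory_detected: int
    n_inhibitory_detected: int


def _region_mean_linear(m: ProteinMatrix, meta: pd.DataFrame,
                        genes: tuple[str, ...]) -> pd.DataFrame:
    """Per-(region, hemisphere) mean linear intensity per gene.

    Accepts log2 or linear matrices; log2 values are exponentiated before
    averaging since sums of log intensities are not meaningful.
    """
    validate_sample_meta(meta)
    present = [g for g in genes if g in m.values.index]
    vals = m.values.loc[present].to_numpy(dtype=float)
    if m.is_log2:
        vals = np.exp2(vals)
    else:
        vals = np.where(vals > 0, vals, np.nan)
    groups = group_labels(meta)
    out = {}
    for g in groups.unique():
        cols_idx = [m.values.columns.get_loc(s)
                    for s in groups.index[groups == g]]
        with np.errstate(invalid="ignore"):
            out[g] = np.nanmean(vals[:, cols_idx], axis=1)
    return pd.DataFrame(out, index=present)


def ei_ratio(m: ProteinMatrix, meta: pd.DataFrame,
             sets: EIGeneSets | None = None) -> pd.DataFrame:
    """E/I expression ratio per region x hemisphere.

    Sums region-mean linear intensities over the detected members of each
    set.  Raises if no excitatory member is detected or the inhibitory sum
    is zero anywhere.
    """
    sets = sets or EIGeneSets()
    e_means = _region_mean_linear(m, meta, sets.excitatory)
    i_means = _region_mean_linear(m, meta, sets.inhibitory)
    if e_means.empty:
        raise ValueError("no excitatory gene detected in the matrix")
    if i_means.empty:
        raise ValueError("no inhibitory gene detected in the matrix")
    rows = []
    for g in e_means.columns:
        region, hemi = g.rsplit("_", 1)
        e_sum = float(np.nansum(e_means[g]))
        i_sum = float(np.nansum(i_means[g]))
        if i_sum <= 0:
            raise ValueError(f"zero inhibitory sum in group {g}")
        rows.append({
            "region": region, "hemisphere": hemi,
            "e_sum": e_sum, "i_sum": i_sum, "ei_ratio": e_sum / i_sum,
            "n_excitatory_detected": int(e_means[g].notna().sum()),
            "n_inhibitory_detected": int(i_means[g].notna().sum()),
        })
    return pd.DataFrame(rows)


def fc_ei_correlation(strengths: pd.Series, records: pd.DataFrame,
                      hemisphere: str, component: str = "ei_ratio"
                      ) -> tuple[float, float]:
    """Pearson correlation of FC node strength vs E/I ratio per hemisphere.

    ``strengths`` is indexed by ROI label (``BA22_L`` style); ``component``
    may be ``ei_ratio``, ``e_sum`` or ``i_sum``.
    """
    if component not in ("ei_ratio", "e_sum", "i_sum"):
        raise ValueError(f"unknown component {component!r}")
    sub = records[records["hemisphere"] == hemisphere]
    if sub.empty:
        raise ValueError(f"no records for hemisphere {hemisphere!r}")
    vals = sub.set_index("region")[component]
    labels = [f"{r}_{hemisphere}" for r in vals.index]
    missing = [l for l in labels if l not in strengths.index]
    if missing:
        raise ValueError(f"missing node strengths for {missing}")
    x = strengths.loc[labels].to_numpy(dtype=float)
    y = vals.to_numpy(dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 regions")
    if np.std(y) == 0 or np.std(x) == 0:
        raise ValueError("constant input; correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class CorrelationComparison:
    r_left: float
    r_right: float
    z_left: float
    z_right: float
    delta_z: float
    statistic: float
    p: float
    method: str
    n: int


def _pearson_filon_cov(r12: float, r34: float, r13: float, r14: float,
                       r23: float, r24: float) -> float:
    """Asymptotic n*cov(r12, r34) for non-overlapping dependent correlations
    (Pearson-Filon)."""
    return (0.5 * r12 * r34 * (r13 ** 2 + r14 ** 2 + r23 ** 2 + r24 ** 2)
            + r13 * r24 + r14 * r23
            - (r12 * r13 * r14 + r12 * r23 * r24
               + r34 * r13 * r23 + r34 * r14 * r24))


def compare_correlations(r_left: float, r_right: float, n: int,
                         cross_corrs: tuple[float, float, float, float] | None
                         = None) -> CorrelationComparison:
    """Compare two correlations via Fisher Delta-Z.

    Dependent case (default when ``cross_corrs`` is given): Steiger's Z for
    two non-overlapping correlations measured on the same n units, using the
    Pearson-Filon covariance of the Fisher z's with mean-r pooling.
    ``cross_corrs`` = (r13, r14, r23, r24) for variables 1 = x_left,
    2 = y_left, 3 = x_right, 4 = y_right (so r12 = r_left, r34 = r_right).
    Without ``cross_corrs`` the independent-samples Fisher-z comparison is
    used: Z = (z_l - z_r) / sqrt(2 / (n - 3)).
    """
    for r in (r_left, r_right):
        if not -1 < r < 1:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n < 4:
        raise ValueError("need n >= 4")
    zl, zr = np.arctanh(r_left), np.arctanh(r_right)
    dz = zl - zr
    if cross_corrs is None:
        se = np.sqrt(2.0 / (n - 3))
        z_stat = dz / se
        method = "fisher-independent"
    else:
        r13, r14, r23, r24 = cross_corrs
        rbar = (r_left + r_right) / 2.0
        cov = _pearson_filon_cov(rbar, rbar, r13, r14, r23, r24)
        c = cov / (1.0 - rbar ** 2) ** 2
        c = float(np.clip(c, -0.999999, 0.999999))
        z_stat = dz * np.sqrt((n - 3) / (2.0 - 2.0 * c))
        method = "steiger-dependent"
    p = 2.0 * stats.norm.sf(abs(z_stat))
    return CorrelationComparison(
        r_left=float(r_left), r_right=float(r_right), z_left=float(zl),
        z_right=float(zr), delta_z=float(dz), statistic=float(z_stat),
        p=float(min(p, 1.0)), method=method, n=int(n))


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    return float(stats.pearsonr(a, b).statistic)


def compare_fc_ei_dependence(strength_left: np.ndarray, e_left: np.ndarray,
                             strength_right: np.ndarray, e_right: np.ndarray
                             ) -> CorrelationComparison:
    """Steiger comparison of matched-hemisphere FC-expression correlations.

    The 13 left and right regions are matched pairs, so the left and right
    correlations are dependent; all four cross correlations are computed
    from the data.
    """
    arrays = [np.asarray(v, float) for v in
              (strength_left, e_left, strength_right, e_right)]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("all inputs must share the region count")
    x1, y1, x2, y2 = arrays
    r12 = _corr(x1, y1)
    r34 = _corr(x2, y2)
    cross = (_corr(x1, x2), _corr(x1, y2), _corr(y1, x2), _corr(y1, y2))
    return compare_correlations(r12, r34, n, cross_corrs=cross)


def gene_driver_profile(m: ProteinMatrix, meta: pd.DataFrame,
                        strengths: pd.Series,
                        sets: EIGeneSets | None = None,
                        max_missing_frac: float = 0.5) -> pd.DataFrame:
    """Per-gene lateralised FC-expression profiling, ranked by |Delta-Z|.

    For each set gene: per-hemisphere Pearson r of region-mean linear
    expression vs node strength, Fisher Delta-Z with Steiger p, plus the
    leave-one-out change in the aggregate (set-sum) Delta-Z.  Genes
    undetected in more than half of the region groups are excluded.
    """
    sets = sets or EIGeneSets()
    all_genes = sets.excitatory + sets.inhibitory
    means = _region_mean_linear(m, meta, all_genes)
    if means.empty:
        raise ValueError("no set gene detected")

    hemi_regions = {h: [r for r in REGIONS if f"{r}_{h}" in means.columns]
                    for h in ("L", "R")}
    sl = strengths.loc[[f"{r}_L" for r in hemi_regions["L"]]].to_numpy(float)
    sr = strengths.loc[[f"{r}_R" for r in hemi_regions["R"]]].to_numpy(float)

    def hemi_profile(values: pd.Series, hemi: str) -> np.ndarray:
        return np.array([values.get(f"{r}_{hemi}", np.nan)
                         for r in hemi_regions[hemi]])

    def agg_delta_z(genes: list[str]) -> float:
        present = [g for g in genes if g in means.index]
        if not present:
            raise ValueError("aggregate undefined for an empty gene set")
        el = np.nansum([hemi_profile(means.loc[g], "L") for g in present],
                       axis=0)
        er = np.nansum([hemi_profile(means.loc[g], "R") for g in present],
                       axis=0)
        cmp_ = compare_fc_ei_dependence(sl, el, sr, er)
        return cmp_.delta_z

    rows = []
    for gene in all_genes:
        if gene not in means.index:
            continue
        prof = means.loc[gene]
        frac_missing = prof.isna().mean()
        if frac_missing > max_missing_frac:
            continue
        el = hemi_profile(prof, "L")
        er = hemi_profile(prof, "R")
        okl, okr = ~np.isnan(el), ~np.isnan(er)
        if okl.sum() < 4 or okr.sum() < 4:
            continue
        cmp_ = compare_fc_ei_dependence(sl[okl], el[okl], sr[okr], er[okr])
        gene_set = ("excitatory" if gene in sets.excitatory else "inhibitory")
        members = list(sets.excitatory if gene_set == "excitatory"
                       else sets.inhibitory)
        if len([g for g in members if g in means.index]) < 2:
            raise ValueError(
                f"leave-one-out aggregate undefined: {gene_set} set has a "
                "single detected gene")
        loo = agg_delta_z([g for g in members if g != gene])
        full = agg_delta_z(members)
        rows.append({
            "gene_id": gene, "set": gene_set,
            "r_left": cmp_.r_left, "r_right": cmp_.r_right,
            "delta_z": cmp_.delta_z, "p_steiger": cmp_.p,
            "loo_delta_z_change": full - loo,
        })
    table = pd.DataFrame(rows)
    return table.reindex(table["delta_z"].abs().sort_values(
        ascending=False).index).reset_index(drop=True)
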