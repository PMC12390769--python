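"""Detection filtering, normalization, PCA QC and donor batch correction.

The processing order mirrors standard region-level LFQ practice: filter
proteins with too few detected donors per region, log2-transform and
median-align the sample columns, then remove donor batch effects by
explicit least squares while preserving every region x hemisphere contrast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    ProteinMatrix,
    group_labels,
    validate_sample_meta,
)

DEFAULT_MIN_DONORS = 5


def filter_low_detection(m: ProteinMatrix, meta: pd.DataFrame,
                         min_donors: int = DEFAULT_MIN_DONORS) -> pd.DataFrame:
    """Per (protein, ROI group) detection mask.

    A protein is usable in a region x hemisphere group iff it is detected
    (nonzero) in at least ``min_donors`` donors of that group.  The mask
    depends only on the zero-pattern of the linear-scale matrix.
    """
    if m.is_log2:
        raise ValueError("detection filtering expects the linear-scale matrix")
    validate_sample_meta(meta)
    groups = group_labels(meta)
    n_donors = meta.groupby(["region", "hemisphere"])["donor"].nunique().min()
    if min_donors > n_donors:
        raise ValueError(
            f"min_donors={min_donors} exceeds the {n_donors} donors available")
    detected = m.values > 0
    mask = {}
    for g in groups.unique():
        cols = groups.index[groups == g]
        mask[g] = detected[cols].sum(axis=1) >= min_donors
    return pd.DataFrame(mask)


def normalize_log2_median(m: ProteinMatrix) -> ProteinMatrix:
    """log2-transform and align sample medians.

    Zeros are treated as missing (NaN).  Each sample column is shifted so
    its median equals the global median of the column medians, removing
    per-sample loading differences while keeping the overall scale.
    """
    if m.is_log2:
        raise ValueError("matrix is already on the log2 scale")
    vals = m.values.to_numpy(dtype=float)
    all_zero = (vals <= 0).all(axis=0)
    if all_zero.any():
        bad = m.values.columns[all_zero].tolist()
        raise ValueError(f"sample(s) with no detected proteins: {bad}")
    with np.errstate(divide="ignore"):
        log2 = np.where(vals > 0, np.log2(np.where(vals > 0, vals, 1.0)), np.nan)
    col_medians = np.nanmedian(log2, axis=0)
    target = np.median(col_medians)
    log2 = log2 - col_medians[None, :] + target
    out = pd.DataFrame(log2, index=m.values.index, columns=m.values.columns)
    return ProteinMatrix(out, is_log2=True)


def remove_batch_effect(m: ProteinMatrix, meta: pd.DataFrame,
                        batch: str = "donor") -> ProteinMatrix:
    """Remove the batch (donor) component by per-protein least squares.

    Per protein, log2 values are regressed on batch indicators plus the kept
    region x hemisphere condition indicators; the batch contribution,
    centred within each condition group, is subtracted.  Centring within
    conditions guarantees that every condition-mean contrast is unchanged to
    machine precision even when missingness unbalances the design.
    """
    if not m.is_log2:
        raise ValueError("batch correction expects the log2 matrix")
    validate_sample_meta(meta)
    meta_idx = meta.set_index("sample_id").loc[list(m.sample_ids)]
    batches = meta_idx[batch].astype(str)
    conds = (meta_idx["region"].astype(str) + "_"
             + meta_idx["hemisphere"].astype(str))
    b_levels = sorted(batches.unique())
    if len(b_levels) == 1:
        return m.copy()
    c_levels = sorted(conds.unique())

    # sum-to-zero coded batch columns, treatment-coded condition columns
    n = len(meta_idx)
    xb = np.zeros((n, len(b_levels) - 1))
    for k, lev in enumerate(b_levels[:-1]):
        xb[:, k] = (batches == lev).to_numpy(float)
    xb[(batches == b_levels[-1]).to_numpy(), :] = -1.0
    xc = np.ones((n, len(c_levels)))
    for k, lev in enumerate(c_levels[1:]):
        xc[:, k + 1] = (conds == lev).to_numpy(float)
    design = np.hstack([xb, xc])
    nb = xb.shape[1]
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("batch is confounded with the kept condition "
                         "(rank-deficient design)")

    vals = m.values.to_numpy(dtype=float)
    out = vals.copy()
    observed = ~np.isnan(vals)
    cond_codes = pd.Categorical(conds, categories=c_levels).codes

    # group proteins by missingness pattern so each distinct design is
    # factorised once
    patterns, inverse = np.unique(observed, axis=0, return_inverse=True)
    for p_idx in range(patterns.shape[0]):
        rows = np.flatnonzero(inverse == p_idx)
        keep = patterns[p_idx]
        if keep.sum() < design.shape[1]:
            continue  # too few observations to fit; leave values as-is
        X = design[keep]
        Y = vals[np.ix_(rows, keep)].T
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        batch_part = X[:, :nb] @ beta[:nb]  # (n_obs, n_proteins_in_group)
        # centre the batch contribution within each condition group
        codes = cond_codes[keep]
        for c in np.unique(codes):
            sel = codes == c
            batch_part[sel] -= batch_part[sel].mean(axis=0, keepdims=True)
        sub = out[np.ix_(rows, keep)]
        out[np.ix_(rows, keep)] = sub - batch_part.T

    res = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return ProteinMatrix(res, is_log2=True)


def pca_embedding(m: ProteinMatrix, n_components: int = 2
                  ) -> tuple[pd.DataFrame, np.ndarray]:
    """Centred PCA of samples with per-protein minimum-value imputation.

    Missing entries are filled with the protein's minimum observed value (a
    standard proxy for below-detection intensities) before centring.
    Returns (scores per sample, explained variance ratios).
    """
    vals = m.values.to_numpy(dtype=float).copy()
    if np.isnan(vals).all(axis=1).any():
        raise ValueError("protein with no observed values")
    row_min = np.nanmin(vals, axis=1)
    nan_r, nan_c = np.nonzero(np.isnan(vals))
    vals[nan_r, nan_c] = row_min[nan_r]

    X = vals.T  # samples x proteins
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds the data dimension")
    from sklearn.decomposition import PCA

    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    df = pd.DataFrame(scores, index=m.values.columns,
                      columns=[f"PC{i + 1}" for i in range(n_components)])
    return df, pca.explained_variance_ratio_
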