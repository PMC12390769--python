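"""Inter-donor variability, differential stability and mRNA-protein coupling.

* V_inter: per protein, the median across regions of the between-donor
  coefficient of variation (CV, on normalised linear intensities).
* Differential stability (DS): mean over donor pairs of the Pearson
  correlation between the two donors' regional profiles; high DS means a
  conserved spatial expression pattern.
* mRNA-protein spatial coupling: per-gene Spearman correlation of regional
  mRNA and protein profiles, tested against a spin null (random sphere
  rotations of the ROI coordinates) and classified as Concordant
  (rho >= .50, FDR < .05), Discordant (rho <= -.20, FDR < .05) or Uncoupled.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    ProteinMatrix,
    REGIONS,
    ROIGeometry,
    group_labels,
    validate_sample_meta,
)
from .differential_expression import bh_fdr
from .preprocess import DEFAULT_MIN_DONORS

CONCORDANT_RHO = 0.50
DISCORDANT_RHO = -0.20
COUPLING_ALPHA = 0.05


def protein_cv(m: ProteinMatrix, meta: pd.DataFrame,
               min_donors: int = 2) -> pd.DataFrame:
    """Per-protein, per-ROI-group CV and its median (V_inter).

    CV = sample SD / mean over detected donors, on the normalised linear
    scale (zeros = not detected are excluded).  Groups with fewer than
    ``min_donors`` detected donors give an undefined (NaN) CV and are
    excluded from the V_inter median.
    """
    if m.is_log2:
        raise ValueError("CV is computed on linear-scale intensities")
    validate_sample_meta(meta)
    groups = group_labels(meta)
    vals = m.values
    out = {}
    for g in groups.unique():
        cols = groups.index[groups == g]
        sub = vals[cols].to_numpy(dtype=float)
        sub = np.where(sub > 0, sub, np.nan)
        n_det = (~np.isnan(sub)).sum(axis=1)
        mean = np.nanmean(np.where(n_det[:, None] >= min_donors, sub, np.nan),
                          axis=1)
        sd = np.nanstd(np.where(n_det[:, None] >= min_donors, sub, np.nan),
                       axis=1, ddof=1)
        cv = np.where((n_det >= min_donors) & (mean > 0), sd / mean, np.nan)
        out[f"cv_{g}"] = cv
    table = pd.DataFrame(out, index=vals.index)
    table["v_inter"] = table.median(axis=1, skipna=True)
    return table


def differential_stability(m: ProteinMatrix, meta: pd.DataFrame,
                           hemisphere: str | None = "L",
                           min_common_regions: int = 3) -> pd.Series:
    """Per-protein DS: mean pairwise donor-profile Pearson correlation.

    Profiles are the per-donor regional vectors (default scope: the 13
    regions of one hemisphere; ``hemisphere=None`` uses all 26 ROIs).
    Donor pairs sharing fewer than ``min_common_regions`` detected regions
    are skipped; proteins with no usable pair are omitted.
    """
    validate_sample_meta(meta)
    sub_meta = meta if hemisphere is None else meta[
        meta["hemisphere"] == hemisphere]
    donors = sorted(sub_meta["donor"].unique())
    if len(donors) < 2:
        raise ValueError("need at least two donors")
    region_cols = sorted(sub_meta["region"].unique(), key=REGIONS.index)

    vals = m.values.to_numpy(dtype=float)
    if not m.is_log2:
        vals = np.where(vals > 0, vals, np.nan)
    col_pos = {c: i for i, c in enumerate(m.values.columns)}
    # donor -> (n_proteins, n_regions) profile array
    profiles = {}
    for d in donors:
        prof = np.full((vals.shape[0], len(region_cols)), np.nan)
        dm = sub_meta[sub_meta["donor"] == d]
        for _, row in dm.iterrows():
            r_idx = region_cols.index(row["region"])
            prof[:, r_idx] = vals[:, col_pos[row["sample_id"]]]
        profiles[d] = prof

    n_prot = vals.shape[0]
    acc = np.zeros(n_prot)
    npair = np.zeros(n_prot)
    for d1, d2 in itertools.combinations(donors, 2):
        a, b = profiles[d1], profiles[d2]
        ok = ~np.isnan(a) & ~np.isnan(b)
        n_common = ok.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            am = np.where(ok, a, 0.0)
            bm = np.where(ok, b, 0.0)
            n = n_common.astype(float)
            n_safe = np.where(n > 0, n, 1.0)
            ma = am.sum(axis=1) / n_safe
            mb = bm.sum(axis=1) / n_safe
            da = np.where(ok, a - ma[:, None], 0.0)
            db = np.where(ok, b - mb[:, None], 0.0)
            cov = (da * db).sum(axis=1)
            denom = np.sqrt((da ** 2).sum(axis=1) * (db ** 2).sum(axis=1))
            r = np.where(denom > 0, cov / denom, np.nan)
        good = (n_common >= min_common_regions) & ~np.isnan(r)
        acc[good] += r[good]
        npair[good] += 1
    ds = np.where(npair > 0, acc / np.where(npair > 0, npair, 1), np.nan)
    res = pd.Series(ds, index=m.values.index, name="ds")
    return res.dropna()


# ---------------------------------------------------------------------------
# spin test


def _random_rotations(n_rot: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform SO(3) samples via QR of Gaussian matrices (det sign fixed)."""
    g = rng.normal(size=(n_rot, 3, 3))
    q, r = np.linalg.qr(g)
    diag_sign = np.sign(np.einsum("nii->ni", r))
    diag_sign[diag_sign == 0] = 1.0
    q = q * diag_sign[:, None, :]
    det = np.linalg.det(q)
    q[det < 0, :, 2] *= -1.0
    return q


def _greedy_assignment(arc: np.ndarray) -> np.ndarray:
    """One-to-one assignment by increasing arc distance (greedy).

    arc[i, j] = distance of rotated ROI i to original ROI j; returns perm
    with perm[i] = assigned original index.
    """
    n = arc.shape[0]
    order = np.argsort(arc, axis=None, kind="stable")
    perm = np.full(n, -1)
    used_rot = np.zeros(n, dtype=bool)
    used_orig = np.zeros(n, dtype=bool)
    filled = 0
    for flat in order:
        i, j = divmod(int(flat), n)
        if used_rot[i] or used_orig[j]:
            continue
        perm[i] = j
        used_rot[i] = used_orig[j] = True
        filled += 1
        if filled == n:
            break
    return perm


def spin_permutations(geom: ROIGeometry, n_rot: int, seed: int) -> np.ndarray:
    """(n_rot, n_roi) index array of rotation-induced ROI permutations.

    Each draw applies one uniform random rotation to the left-hemisphere
    coordinates and its x-mirrored counterpart to the right hemisphere, then
    reassigns each rotated ROI to the nearest original ROI of the same
    hemisphere, one-to-one greedily by increasing arc distance.
    """
    coords = geom.coords
    # duplicate-coordinate guard: assignment would be ill-defined
    gram = coords @ coords.T
    np.fill_diagonal(gram, -np.inf)
    if np.any(gram > 1 - 1e-12):
        raise ValueError("duplicate ROI coordinates; spin assignment undefined")

    hemis = np.asarray(geom.hemispheres)
    rng = np.random.default_rng(seed)
    rots = _random_rotations(n_rot, rng)
    mirror = np.diag([-1.0, 1.0, 1.0])

    perms = np.empty((n_rot, geom.n_rois), dtype=int)
    for hemi in np.unique(hemis):
        sel = np.flatnonzero(hemis == hemi)
        sub = coords[sel]
        if hemi == "R":
            rmats = np.einsum("ij,njk,kl->nil", mirror, rots, mirror)
        else:
            rmats = rots
        rotated = np.einsum("nij,kj->nki", rmats, sub)  # (n_rot, n_sub, 3)
        cosang = np.clip(np.einsum("nki,li->nkl", rotated, sub), -1.0, 1.0)
        arc = np.arccos(cosang)
        for t in range(n_rot):
            perms[t, sel] = sel[_greedy_assignment(arc[t])]
    return perms


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    return float(stats.spearmanr(x, y).statistic)


def spin_test(map_x: np.ndarray, map_y: np.ndarray, geom: ROIGeometry,
              n_rot: int = 1000, seed: int = 0, stat: str = "spearman",
              null: str = "spin") -> tuple[float, float]:
    """Spatial-permutation test of the correlation between two ROI maps.

    The observed statistic (Spearman by default, Pearson optional) is
    compared two-sidedly against a null built by spinning ``map_x``'s ROI
    assignment: p = (1 + #{|null| >= |obs|}) / (1 + n_rot).  ``null`` may be
    ``spin`` (rotation-induced permutations) or ``permute`` (plain label
    permutation fallback, useful with very few ROIs).
    """
    x = np.asarray(map_x, dtype=float)
    y = np.asarray(map_y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("maps must be 1-D and share the ROI set")
    if n_rot < 99:
        raise ValueError("need at least 99 rotations")
    corr = _spearman if stat == "spearman" else (
        lambda a, b: float(stats.pearsonr(a, b).statistic))
    if stat not in ("spearman", "pearson"):
        raise ValueError(f"unknown statistic {stat!r}")

    obs = corr(x, y)
    if null == "spin":
        if len(x) != geom.n_rois:
            raise ValueError("map length does not match geometry ROI count")
        perms = spin_permutations(geom, n_rot, seed)
    elif null == "permute":
        rng = np.random.default_rng(seed)
        perms = np.stack([rng.permutation(len(x)) for _ in range(n_rot)])
    else:
        raise ValueError(f"unknown null type {null!r}")

    null_stats = np.array([corr(x[perm], y) for perm in perms])
    p = (1 + np.sum(np.abs(null_stats) >= abs(obs) - 1e-12)) / (1 + n_rot)
    return obs, float(p)


def classify_concordance(rho: float, q: float) -> str:
    """Concordant / Discordant / Uncoupled classification of a gene."""
    if np.isnan(rho):
        return "Uncoupled"
    if rho >= CONCORDANT_RHO and q < COUPLING_ALPHA:
        return "Concordant"
    if rho <= DISCORDANT_RHO and q < COUPLING_ALPHA:
        return "Discordant"
    return "Uncoupled"


@dataclass
class CouplingSummary:
    records: pd.DataFrame
    counts: dict[str, int]
    percentages: dict[str, float]


def class_percentages(counts: dict[str, int]) -> dict[str, float]:
    total = sum(counts.values())
    if total == 0:
        return {k: float("nan") for k in counts}
    return {k: 100.0 * v / total for k, v in counts.items()}


def mrna_protein_coupling(protein_means: pd.DataFrame, mrna: pd.DataFrame,
                          geom: ROIGeometry, n_rot: int = 1000,
                          seed: int = 0) -> CouplingSummary:
    """Gene-wise regional mRNA-protein Spearman coupling with spin FDR.

    ``protein_means`` and ``mrna`` are genes x regions tables sharing the
    region columns; the spin null is computed once (the same permutation set
    is applied to every gene, as is standard for map-level spin tests) and
    BH-FDR is taken across genes.  Genes with a constant profile in either
    layer get an undefined rho and are classed Uncoupled.
    """
    shared = protein_means.index.intersection(mrna.index)
    if shared.empty:
        raise ValueError("no shared genes between protein and mRNA tables")
    regions = [c for c in protein_means.columns if c in mrna.columns]
    if len(regions) != geom.n_rois:
        raise ValueError("region set does not match the geometry")
    P = protein_means.loc[shared, regions].to_numpy(dtype=float)
    M = mrna.loc[shared, regions].to_numpy(dtype=float)

    rp = stats.rankdata(P, axis=1)
    rm = stats.rankdata(M, axis=1)
    defined = (P.std(axis=1) > 0) & (M.std(axis=1) > 0) \
        & ~np.isnan(P).any(axis=1) & ~np.isnan(M).any(axis=1)

    def _rowwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        a = a - a.mean(axis=1, keepdims=True)
        b = b - b.mean(axis=1, keepdims=True)
        denom = np.sqrt((a ** 2).sum(axis=1) * (b ** 2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, (a * b).sum(axis=1) / denom, np.nan)

    rho = _rowwise_corr(rp, rm)
    rho[~defined] = np.nan

    perms = spin_permutations(geom, n_rot, seed)
    exceed = np.zeros(len(shared))
    abs_obs = np.abs(rho)
    for perm in perms:
        null_rho = _rowwise_corr(rp[:, perm], rm)
        exceed += (np.abs(null_rho) >= abs_obs - 1e-12)
    p_spin = (1 + exceed) / (1 + n_rot)
    p_spin[~defined] = 1.0

    q = bh_fdr(p_spin)
    classes = [classify_concordance(r, qq) for r, qq in zip(rho, q)]
    records = pd.DataFrame({
        "gene_id": shared,
        "rho": rho,
        "p_spin": p_spin,
        "q": q,
        "coupling_class": classes,
    }).reset_index(drop=True)
    counts = {c: int((records["coupling_class"] == c).sum())
              for c in ("Concordant", "Discordant", "Uncoupled")}
    return CouplingSummary(records=records, counts=counts,
                           percentages=class_percentages(counts))
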