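"""Synthetic study-data generator with known ground truth.

Emulates the structure of the study's three data layers so that every
downstream estimator can be tested against planted effects:

* a label-free-quantification (LFQ) proteome over 13 bilateral
  language-related Brodmann areas x 10 donors, with region-specific
  signatures, left-right asymmetries and donor batch effects;
* subject-level ROI time series and streamline counts whose pairwise
  coupling increases with proteomic similarity, carries a homotopic
  (left-right homologue) boost, and encodes a lateralised
  excitatory-expression/connectivity gradient;
* a patient/control cohort with planted grey-matter-volume (GMV) group
  effects and GMV-language-score correlations.

All generators are pure functions of (config, seed): identical inputs give
byte-identical outputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import (
    HEMISPHERES,
    N_REGIONS,
    N_ROIS,
    REGIONS,
    ROI_LABELS,
    ProteinMatrix,
    ROIGeometry,
    ROITimeSeries,
    StreamlineTable,
    roi_label,
)
from .gene_sets import EXCITATORY_GENES, INHIBITORY_GENES

# rng stream ids so each generator stage draws from an independent stream
_STREAM_PROTEOME = 11
_STREAM_CONNECTOME = 12
_STREAM_GEOMETRY = 13
_STREAM_MRNA = 14
_STREAM_COHORT = 15


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-scale defaults for the synthetic generators.

    Proteome: 4415 proteins x 13 regions x 2 hemispheres x 10 donors on the
    log2 LFQ scale (donor-to-donor noise SD 0.5 log2 units, 5% of entries
    missing).  Connectome: 90 subjects x 200 time points over the 26 ROIs.
    Cohort: 52 patients vs 30 controls.
    """

    seed: int = 0
    # proteome
    n_proteins: int = 4415
    n_donors: int = 10
    baseline_mean: float = 22.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.5
    missing_rate: float = 0.05
    missing_mechanism: str = "mcar"  # or "abundance"
    region_effect_frac: float = 0.05
    region_effect_sd: float = 1.0
    hemisphere_effect_frac: float = 0.02
    hemisphere_effect_sd: float = 0.8
    # donor batch effects: a global per-donor loading shift plus a
    # protein-specific component (the part median alignment cannot remove)
    donor_offset_sd: float = 0.6
    donor_offset_jitter: float = 0.3
    # E/I lateralisation planting
    # calibrated so realized FC vs E/I correlations match the magnitudes the
    # study reports (|r| ~ .65-.79 over 13 regions)
    ei_slope_left: float = 0.9
    ei_slope_right: float = -0.9
    ei_driver_genes: tuple[str, ...] = ("GRIA1", "GRIA4")
    ei_minor_scale: float = 0.3
    # connectome
    n_subjects: int = 90
    n_timepoints: int = 200
    base_weight: float = 0.05
    coupling_slope: float = 0.3
    homotopic_boost: float = 1.0
    gradient_weight: float = 0.15
    ts_noise_sd: float = 1.0
    sc_base: float = 30.0
    sc_slope: float = 4.2
    sc_dispersion: float = 2.0
    area_mean_mm2: float = 78.5
    area_sd_log: float = 0.15
    # cohort
    n_patients: int = 52
    n_controls: int = 30
    gmv_baseline: float = 100.0
    gmv_sd: float = 10.0
    gmv_effect_sd_units: float = 1.0
    gmv_effect_rois: tuple[str, ...] = ("BA22_R", "BA21_R")
    gmv_score_r: float = 0.6
    score_mean_control: float = 95.0
    score_mean_patient: float = 85.0
    score_sd: float = 8.0

    def validate(self) -> None:
        if self.n_proteins < 50:
            raise ValueError("n_proteins must be >= 50")
        if self.n_donors < 4:
            raise ValueError("n_donors must be >= 4")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing rate must lie in [0, 1)")
        if self.missing_mechanism not in ("mcar", "abundance"):
            raise ValueError("missing_mechanism must be 'mcar' or 'abundance'")
        if self.n_subjects < 2 or self.n_timepoints < 50:
            raise ValueError("need >= 2 subjects and >= 50 time points")
        if self.homotopic_boost < 0:
            raise ValueError("homotopic boost must be >= 0")
        if self.n_patients < 3 or self.n_controls < 3:
            raise ValueError("need >= 3 patients and >= 3 controls")
        if not -1 <= self.gmv_score_r <= 1:
            raise ValueError("gmv_score_r must lie in [-1, 1]")


@dataclass
class GroundTruth:
    """Planted effects that determine every downstream expectation."""

    region_signatures: dict[str, np.ndarray]
    hemisphere_effects: np.ndarray  # per-protein left-minus-right shift, log2
    donor_offsets: dict[str, np.ndarray]
    baseline: np.ndarray
    lateralised_profiles: dict[str, np.ndarray]  # gene -> (13 regions, 2 hemis)
    connectivity_gradient: np.ndarray  # per-region latent, standardised
    coupling_slope: float
    homotopic_boost: float
    ei_slopes: tuple[float, float]
    gmv_effects: dict[str, float]
    gmv_score_r: float
    seed: int
    protein_ids: tuple[str, ...] = ()

    def expected_log2(self, protein_idx: np.ndarray | slice,
                      region: str, hemisphere: str, donor: str | None = None
                      ) -> np.ndarray:
        """Noise-free expected log2 abundance for given samples."""
        sign = 0.5 if hemisphere == "L" else -0.5
        mu = (self.baseline[protein_idx]
              + self.region_signatures[region][protein_idx]
              + sign * self.hemisphere_effects[protein_idx])
        if donor is not None:
            mu = mu + self.donor_offsets[donor][protein_idx]
        ids = np.asarray(self.protein_ids)[protein_idx]
        r_idx = REGIONS.index(region)
        h_idx = 0 if hemisphere == "L" else 1
        mu = np.array(mu, dtype=float)
        for k, gid in enumerate(np.atleast_1d(ids)):
            prof = self.lateralised_profiles.get(str(gid))
            if prof is not None:
                mu[k] += prof[r_idx, h_idx]
        return mu


def _protein_ids(n_proteins: int) -> tuple[str, ...]:
    named = EXCITATORY_GENES + INHIBITORY_GENES
    if n_proteins < len(named):
        raise ValueError("n_proteins smaller than the named receptor panel")
    generic = tuple(f"PROT{i:05d}" for i in range(n_proteins - len(named)))
    return named + generic


def _make_ground_truth(config: GeneratorConfig, rng: np.random.Generator
                       ) -> GroundTruth:
    n = config.n_proteins
    ids = _protein_ids(n)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)

    region_signatures: dict[str, np.ndarray] = {}
    for region in REGIONS:
        sig = np.zeros(n)
        k = max(1, int(round(config.region_effect_frac * n)))
        hit = rng.choice(n, size=k, replace=False)
        sig[hit] = rng.normal(0.0, config.region_effect_sd, size=k)
        region_signatures[region] = sig

    hemi = np.zeros(n)
    k = max(1, int(round(config.hemisphere_effect_frac * n)))
    hit = rng.choice(n, size=k, replace=False)
    hemi[hit] = rng.normal(0.0, config.hemisphere_effect_sd, size=k)

    donors = [f"D{i + 1:02d}" for i in range(config.n_donors)]
    donor_offsets = {}
    for d in donors:
        mu_d = rng.normal(0.0, config.donor_offset_sd)
        donor_offsets[d] = mu_d + rng.normal(0.0, config.donor_offset_jitter,
                                             size=n)

    grad = rng.normal(size=N_REGIONS)
    grad = (grad - grad.mean()) / grad.std()

    lateral: dict[str, np.ndarray] = {}
    for gene in EXCITATORY_GENES:
        scale = 1.0 if gene in config.ei_driver_genes else config.ei_minor_scale
        prof = np.zeros((N_REGIONS, 2))
        prof[:, 0] = scale * config.ei_slope_left * grad
        prof[:, 1] = scale * config.ei_slope_right * grad
        lateral[gene] = prof

    return GroundTruth(
        region_signatures=region_signatures,
        hemisphere_effects=hemi,
        donor_offsets=donor_offsets,
        baseline=baseline,
        lateralised_profiles=lateral,
        connectivity_gradient=grad,
        coupling_slope=config.coupling_slope,
        homotopic_boost=config.homotopic_boost,
        ei_slopes=(config.ei_slope_left, config.ei_slope_right),
        gmv_effects={r: config.gmv_effect_sd_units for r in config.gmv_effect_rois},
        gmv_score_r=config.gmv_score_r,
        seed=config.seed,
        protein_ids=ids,
    )


def generate_proteome(config: GeneratorConfig
                      ) -> tuple[ProteinMatrix, pd.DataFrame, GroundTruth]:
    """Simulate the LFQ protein matrix with sample metadata.

    log2 abundance = baseline + region signature + hemisphere effect +
    lateralised receptor profile + donor offset + Gaussian noise; values are
    exponentiated to the linear intensity scale and missing entries are
    stored as zero (the downstream filter treats zero as not-detected).
    """
    config.validate()
    rng = np.random.default_rng([_STREAM_PROTEOME, config.seed])
    gt = _make_ground_truth(config, rng)
    n = config.n_proteins
    donors = list(gt.donor_offsets)

    ei_rows = {gid: i for i, gid in enumerate(gt.protein_ids)
               if gid in gt.lateralised_profiles}

    cols: list[str] = []
    meta_rows: list[dict[str, str]] = []
    log2 = np.empty((n, len(donors) * N_ROIS))
    j = 0
    for donor in donors:
        for h_idx, hemi in enumerate(HEMISPHERES):
            sign = 0.5 if hemi == "L" else -0.5
            for r_idx, region in enumerate(REGIONS):
                mu = (gt.baseline
                      + gt.region_signatures[region]
                      + sign * gt.hemisphere_effects
                      + gt.donor_offsets[donor])
                col = mu.copy()
                for gid, row in ei_rows.items():
                    col[row] += gt.lateralised_profiles[gid][r_idx, h_idx]
                log2[:, j] = col
                sid = f"{donor}_{region}_{hemi}"
                cols.append(sid)
                meta_rows.append({"sample_id": sid, "donor": donor,
                                  "region": region, "hemisphere": hemi})
                j += 1

    log2 = log2 + rng.normal(0.0, config.noise_sd, size=log2.shape)
    intensity = np.exp2(log2)

    if config.missing_rate > 0:
        if config.missing_mechanism == "mcar":
            miss = rng.random(size=log2.shape) < config.missing_rate
        else:
            # abundance-dependent: logistic in the log2 value, calibrated so
            # the marginal missing fraction matches missing_rate
            z = (log2 - np.mean(log2)) / np.std(log2)
            shift = float(np.quantile(-z, 1 - config.missing_rate))
            prob = 1.0 / (1.0 + np.exp(2.0 * (z + shift)))
            prob *= config.missing_rate / max(prob.mean(), 1e-12)
            miss = rng.random(size=log2.shape) < np.clip(prob, 0, 1)
        intensity[miss] = 0.0

    values = pd.DataFrame(intensity, index=list(gt.protein_ids), columns=cols)
    meta = pd.DataFrame(meta_rows)
    return ProteinMatrix(values, is_log2=False), meta, gt


def expected_region_profiles(gt: GroundTruth) -> pd.DataFrame:
    """Noise-free expected log2 profile per ROI (proteins x 26 ROIs)."""
    n = len(gt.baseline)
    out = {}
    for hemi in HEMISPHERES:
        for region in REGIONS:
            out[roi_label(region, hemi)] = gt.expected_log2(
                np.arange(n), region, hemi)
    return pd.DataFrame(out, index=list(gt.protein_ids))[list(ROI_LABELS)]


def similarity_from_groundtruth(gt: GroundTruth) -> np.ndarray:
    """26x26 Spearman similarity of expected region profiles."""
    from scipy.stats import spearmanr

    prof = expected_region_profiles(gt).to_numpy()
    rho = spearmanr(prof, axis=0).statistic
    return np.asarray(rho)


def _pair_index(n: int) -> list[tuple[int, int]]:
    return list(itertools.combinations(range(n), 2))


def connectivity_weights(config: GeneratorConfig, similarity: np.ndarray,
                         gt: GroundTruth) -> np.ndarray:
    """Latent mixing weight per ROI pair (symmetric, zero diagonal).

    w_ij = base + slope * rank(similarity) + boost * homotopic +
    gradient_weight * (g_i + g_j), clipped at zero.  Ranks are scaled to
    [0, 1] over the distinct unordered pairs.
    """
    sim = np.asarray(similarity, dtype=float)
    if sim.shape != (N_ROIS, N_ROIS) or not np.allclose(sim, sim.T):
        raise ValueError(f"similarity matrix must be {N_ROIS}x{N_ROIS} symmetric")
    pairs = _pair_index(N_ROIS)
    vals = np.array([sim[i, j] for i, j in pairs])
    order = np.argsort(np.argsort(vals, kind="stable"), kind="stable")
    simrank = order / max(len(pairs) - 1, 1)

    grad26 = np.concatenate([gt.connectivity_gradient, gt.connectivity_gradient])
    w = np.zeros((N_ROIS, N_ROIS))
    for k, (i, j) in enumerate(pairs):
        homol = (j == i + N_REGIONS)
        wij = (config.base_weight
               + gt.coupling_slope * simrank[k]
               + (gt.homotopic_boost if homol else 0.0)
               + config.gradient_weight * (grad26[i] + grad26[j]))
        w[i, j] = w[j, i] = max(wij, 0.0)
    return w


def generate_connectome(config: GeneratorConfig, similarity: np.ndarray,
                        gt: GroundTruth
                        ) -> tuple[list[ROITimeSeries], StreamlineTable]:
    """Simulate subject ROI time series and a streamline-count table.

    Each ROI pair (i, j) shares a latent signal entering both ROIs with
    weight sqrt(w_ij) on top of unit private noise, so every subject's FC is
    a valid correlation matrix by construction with population
    r_ij = w_ij / sqrt((1 + sum_k w_ik)(1 + sum_k w_jk)).  Streamline counts
    are negative-binomial with log-link mean sc_base * exp(sc_slope * w_ij).
    """
    config.validate()
    rng = np.random.default_rng([_STREAM_CONNECTOME, config.seed])
    w = connectivity_weights(config, similarity, gt)
    pairs = _pair_index(N_ROIS)

    # mixing matrix: private noise plus one column per shared pair latent
    mix = np.zeros((N_ROIS, N_ROIS + len(pairs)))
    mix[:, :N_ROIS] = np.eye(N_ROIS) * config.ts_noise_sd
    for k, (i, j) in enumerate(pairs):
        s = np.sqrt(w[i, j])
        mix[i, N_ROIS + k] = s
        mix[j, N_ROIS + k] = s

    subjects = []
    for s_idx in range(config.n_subjects):
        z = rng.normal(size=(config.n_timepoints, mix.shape[1]))
        ts = z @ mix.T
        subjects.append(ROITimeSeries(subject_id=f"S{s_idx + 1:03d}", values=ts))

    mu = config.sc_base * np.exp(config.sc_slope * w)
    k_disp = config.sc_dispersion
    counts = np.zeros((N_ROIS, N_ROIS))
    for i, j in pairs:
        p = k_disp / (k_disp + mu[i, j])
        c = rng.negative_binomial(k_disp, p)
        counts[i, j] = counts[j, i] = c

    areas = pd.Series(
        config.area_mean_mm2
        * np.exp(rng.normal(0.0, config.area_sd_log, size=N_ROIS)),
        index=list(ROI_LABELS),
    )
    return subjects, StreamlineTable(counts=counts, areas=areas)


def generate_roi_geometry(n_rois: int = N_REGIONS, seed: int = 0,
                          labels: tuple[str, ...] | None = None) -> ROIGeometry:
    """Random ROI centroids on the unit sphere, plus mirrored partners.

    ``n_rois`` base ROIs are placed on the x > 0 half-sphere; each gets a
    partner mirrored through the x = 0 plane (sign of x flipped), giving
    2 * n_rois ROIs in canonical left-then-right order.
    """
    if n_rois < 3:
        raise ValueError("need at least 3 ROIs")
    rng = np.random.default_rng([_STREAM_GEOMETRY, seed])
    xyz = rng.normal(size=(n_rois, 3))
    xyz /= np.linalg.norm(xyz, axis=1, keepdims=True)
    xyz[:, 0] = np.abs(xyz[:, 0])  # one hemisphere: x > 0
    mirrored = xyz * np.array([-1.0, 1.0, 1.0])
    coords = np.vstack([xyz, mirrored])
    areas = 78.5 * np.exp(rng.normal(0.0, 0.15, size=2 * n_rois))
    if labels is None:
        if n_rois == N_REGIONS:
            labels = ROI_LABELS
        else:
            labels = tuple(f"ROI{i}_L" for i in range(n_rois)) + tuple(
                f"ROI{i}_R" for i in range(n_rois))
    hemis = tuple("L" for _ in range(n_rois)) + tuple("R" for _ in range(n_rois))
    return ROIGeometry(labels=tuple(labels), coords=coords, areas=areas,
                       hemispheres=hemis)


def generate_mrna(proteome: ProteinMatrix, meta: pd.DataFrame,
                  per_gene_rho: dict[str, float], config: GeneratorConfig,
                  hemisphere: str = "L") -> pd.DataFrame:
    """Regional mRNA profiles with planted protein-mRNA rank coupling.

    Gaussian-copula construction on the 13-region protein mean profile:
    each gene's mRNA normal scores are rho_pearson * (protein normal
    scores) + noise, with rho_pearson = 2 sin(pi * rho_s / 6) chosen so the
    population Spearman correlation equals the planted value.  Genes absent
    from ``per_gene_rho`` get rho 0.
    """
    for g, r in per_gene_rho.items():
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"planted rho for {g} outside [-1, 1]")
    rng = np.random.default_rng([_STREAM_MRNA, config.seed])

    if not proteome.is_log2:
        # couple to the normalized regional abundance, not donor-batch
        # artifacts: median-align columns exactly as the analysis does
        from .preprocess import normalize_log2_median

        proteome = normalize_log2_median(proteome)
    vals = proteome.values.to_numpy(dtype=float)
    cols = pd.Index(proteome.sample_ids)
    meta_idx = meta.set_index("sample_id")
    prof = np.full((vals.shape[0], N_REGIONS), np.nan)
    for r_idx, region in enumerate(REGIONS):
        sel = [k for k, sid in enumerate(cols)
               if meta_idx.loc[sid, "region"] == region
               and meta_idx.loc[sid, "hemisphere"] == hemisphere]
        prof[:, r_idx] = np.nanmean(vals[:, sel], axis=1)

    from scipy.stats import norm, rankdata

    n_reg = N_REGIONS
    ranks = rankdata(prof, axis=1)
    zp = norm.ppf(ranks / (n_reg + 1))

    out = np.empty_like(zp)
    genes = list(proteome.protein_ids)
    for gi, gene in enumerate(genes):
        rho_s = float(per_gene_rho.get(gene, 0.0))
        rho_p = 2.0 * np.sin(np.pi * rho_s / 6.0)
        eps = rng.normal(size=n_reg)
        out[gi] = rho_p * zp[gi] + np.sqrt(max(0.0, 1.0 - rho_p ** 2)) * eps
    return pd.DataFrame(out, index=genes, columns=list(REGIONS))


def generate_cohort(config: GeneratorConfig, gt: GroundTruth) -> pd.DataFrame:
    """Patient/control cohort with planted GMV effects and GMV-score coupling.

    Per-subject ROI GMV = control mean + (patients only) planted shift in
    units of the GMV SD + Gaussian noise.  Linguistic scores of patients
    correlate with the mean GMV over the planted ROIs at ``gmv_score_r``;
    controls score higher on average, emulating the patient deficit.
    """
    config.validate()
    rng = np.random.default_rng([_STREAM_COHORT, config.seed])
    n_p, n_c = config.n_patients, config.n_controls
    n = n_p + n_c
    groups = np.array(["patient"] * n_p + ["control"] * n_c)

    gmv = rng.normal(config.gmv_baseline, config.gmv_sd, size=(n, N_ROIS))
    labels = list(ROI_LABELS)
    for roi, eff in gt.gmv_effects.items():
        col = labels.index(roi)
        gmv[:n_p, col] += eff * config.gmv_sd

    target_cols = [labels.index(r) for r in gt.gmv_effects] or [
        labels.index("BA22_R")]
    target = gmv[:, target_cols].mean(axis=1)
    zt = (target - target.mean()) / target.std(ddof=0)

    score_names = ("AQ", "spontaneous_speech", "comprehension", "repetition",
                   "naming")
    r = gt.gmv_score_r
    scores = {}
    for name in score_names:
        eps = rng.normal(size=n)
        mixed = r * zt + np.sqrt(max(0.0, 1.0 - r ** 2)) * eps
        base = np.where(groups == "patient", config.score_mean_patient,
                        config.score_mean_control)
        # coupling is planted within the patient group only
        vals = base + config.score_sd * np.where(
            groups == "patient", mixed, rng.normal(size=n))
        scores[name] = vals

    age = np.where(groups == "patient",
                   rng.normal(48.4, 12.0, size=n),
                   rng.normal(48.3, 6.4, size=n))
    sex = rng.choice(["M", "F"], size=n)
    tumour = np.where(groups == "patient",
                      np.exp(rng.normal(3.0, 0.6, size=n)), np.nan)

    table = pd.DataFrame({
        "subject_id": [f"P{i + 1:03d}" if g == "patient" else f"C{i + 1:03d}"
                       for i, g in enumerate(groups)],
        "group": groups,
        "age": np.round(age, 1),
        "sex": sex,
        "tumour_volume": np.round(tumour, 2),
    })
    for k, roi in enumerate(labels):
        table[f"gmv_{roi}"] = gmv[:, k]
    for name in score_names:
        table[name] = np.round(scores[name], 2)
    return table
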