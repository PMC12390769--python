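"""End-to-end orchestration: simulate/load -> preprocess -> QC -> DE ->
connectome -> coupling -> E/I -> cohort reorganisation.

A run is driven by a single nested config (YAML on disk); every stage
writes its outputs under the run directory and contributes a summary block
to the machine-readable JSON report.  Fixed seeds make reports
reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from . import connectome as cn
from . import coupling as cp
from . import differential_expression as de
from . import ei_balance as ei
from . import io
from . import preprocess as pp
from . import reorganisation as ro
from . import synthetic_data as sd
from . import variability as vb
from .datatypes import ROI_LABELS
from .gene_sets import EIGeneSets

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulation": {},          # GeneratorConfig overrides; {} = defaults
    "inputs": {},              # alternatively: paths to matrix/meta/... files
    "thresholds": {
        "dep_p": 0.05,
        "dep_log2fc": 0.1,
        "fdr_alpha": 0.05,
        "ds_high": 0.70,
        "ds_low": -0.30,
        "concordant_rho": 0.50,
        "discordant_rho": -0.20,
    },
    "de": {"test": "wilcoxon", "min_donors": 5},
    "fc": {"aggregation": "fisher", "strength_scope": "all"},
    "spin": {"n_rot": 1000, "null": "spin"},
    # planted coupling strengths are calibrated so the recovered class counts
    # resemble the observed Concordant/Discordant proportions; with only 13
    # regions, weaker couplings are not reliably detectable by a two-sided
    # spatial-permutation test (see docs/methods.md)
    "mrna": {"n_concordant": 60, "rho_concordant": 0.95,
             "n_discordant": 240, "rho_discordant": -0.95},
    "cohort": {"covariates": ["age", "sex"]},
}

_RANGES = {
    ("thresholds", "dep_p"): (0.0, 1.0),
    ("thresholds", "fdr_alpha"): (0.0, 1.0),
    ("thresholds", "dep_log2fc"): (0.0, float("inf")),
    ("thresholds", "ds_high"): (-1.0, 1.0),
    ("thresholds", "ds_low"): (-1.0, 1.0),
    ("thresholds", "concordant_rho"): (-1.0, 1.0),
    ("thresholds", "discordant_rho"): (-1.0, 1.0),
    ("spin", "n_rot"): (99, float("inf")),
}


def merged_config(config: dict[str, Any] | None) -> dict[str, Any]:
    """Deep-merge user config over the defaults (unknown keys kept)."""
    out = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key].update(val)
        else:
            out[key] = val
    return out


def validate_config(config: dict[str, Any]) -> list[str]:
    """Schema/range findings; never mutates or raises."""
    findings: list[str] = []
    cfg = merged_config(config)
    for (section, key), (lo, hi) in _RANGES.items():
        val = cfg.get(section, {}).get(key)
        if val is None:
            continue
        if not (lo <= float(val) <= hi):
            findings.append(f"{section}.{key}={val} out of range [{lo}, {hi}]")
    for key in (config or {}):
        if key not in DEFAULT_CONFIG:
            findings.append(f"unknown config key {key!r}")
    ei_sets = cfg.get("ei", {})
    if "excitatory" in ei_sets and not ei_sets["excitatory"]:
        findings.append("empty excitatory gene list")
    if "inhibitory" in ei_sets and not ei_sets["inhibitory"]:
        findings.append("empty inhibitory gene list")
    de_cfg = cfg.get("de", {})
    if de_cfg.get("test") not in ("wilcoxon", "t"):
        findings.append(f"de.test={de_cfg.get('test')!r} not recognised")
    if cfg.get("simulation") is None and not cfg.get("inputs"):
        findings.append("neither a simulation block nor input paths given")
    return findings


def _simulate(cfg: dict[str, Any], out: Path) -> dict[str, Any]:
    sim_overrides = dict(cfg.get("simulation") or {})
    gen_cfg = sd.GeneratorConfig(seed=cfg["seed"], **sim_overrides)
    matrix, meta, gt = sd.generate_proteome(gen_cfg)
    sim = sd.similarity_from_groundtruth(gt)
    subjects, streamlines = sd.generate_connectome(gen_cfg, sim, gt)
    geom = sd.generate_roi_geometry(seed=cfg["seed"])

    rng = np.random.default_rng([21, cfg["seed"]])
    mrna_cfg = cfg["mrna"]
    genes = list(matrix.protein_ids)
    chosen = rng.choice(len(genes),
                        size=mrna_cfg["n_concordant"] + mrna_cfg["n_discordant"],
                        replace=False)
    per_gene_rho = {}
    for k, gi in enumerate(chosen):
        rho = (mrna_cfg["rho_concordant"] if k < mrna_cfg["n_concordant"]
               else mrna_cfg["rho_discordant"])
        per_gene_rho[genes[gi]] = rho
    mrna = sd.generate_mrna(matrix, meta, per_gene_rho, gen_cfg)
    cohort = sd.generate_cohort(gen_cfg, gt)

    io.write_protein_matrix(matrix, out / "protein_matrix.tsv")
    io.write_sample_meta(meta, out / "sample_meta.tsv")
    io.write_streamlines(streamlines, out / "streamline_counts.tsv",
                         out / "roi_areas.tsv")
    io.write_geometry(geom, out / "roi_geometry.tsv")
    io.write_mrna(mrna, out / "mrna_matrix.tsv")
    io.write_table(cohort, out / "cohort.tsv")
    return {"matrix": matrix, "meta": meta, "gt": gt, "subjects": subjects,
            "streamlines": streamlines, "geom": geom, "mrna": mrna,
            "cohort": cohort,
            "planted_rho_genes": per_gene_rho}


def _load(cfg: dict[str, Any]) -> dict[str, Any]:
    inputs = cfg["inputs"]
    needed = ("matrix", "meta")
    for key in needed:
        if key not in inputs:
            raise ValueError(f"stage 'inputs': missing input path {key!r}")
    data: dict[str, Any] = {
        "matrix": io.read_protein_matrix(inputs["matrix"], is_log2=False),
        "meta": io.read_sample_meta(inputs["meta"]),
        "gt": None,
    }
    if "timeseries_dir" in inputs:
        data["subjects"] = io.read_timeseries_dir(inputs["timeseries_dir"])
    if "streamlines" in inputs and "areas" in inputs:
        data["streamlines"] = io.read_streamlines(inputs["streamlines"],
                                                  inputs["areas"])
    if "geometry" in inputs:
        data["geom"] = io.read_geometry(inputs["geometry"])
    if "mrna" in inputs:
        data["mrna"] = io.read_mrna(inputs["mrna"])
    if "cohort" in inputs:
        data["cohort"] = io.read_cohort(inputs["cohort"])
    return data


def run_all(config: dict[str, Any] | None, out_dir: str | Path) -> dict[str, Any]:
    """Execute all stages in dependency order; returns the report dict."""
    cfg = merged_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"version": __version__, "config": cfg,
                              "stages": {}, "warnings": [], "files": []}

    def _record(path: Path) -> None:
        report["files"].append(str(path.relative_to(out)))

    # --- stage: inputs -----------------------------------------------------
    try:
        if cfg.get("inputs"):
            data = _load(cfg)
        elif cfg.get("simulation") is not None:
            data = _simulate(cfg, out)
            for name in ("protein_matrix.tsv", "sample_meta.tsv",
                         "streamline_counts.tsv", "roi_areas.tsv",
                         "roi_geometry.tsv", "mrna_matrix.tsv", "cohort.tsv"):
                _record(out / name)
        else:
            raise ValueError("no simulation block and no input paths")
    except Exception as exc:  # noqa: BLE001 - stage-labelled fail-fast
        raise RuntimeError(f"stage 'inputs' failed: {exc}") from exc
    matrix, meta = data["matrix"], data["meta"]
    min_donors = cfg["de"]["min_donors"]

    # --- stage: preprocess -------------------------------------------------
    try:
        mask = pp.filter_low_detection(matrix, meta, min_donors=min_donors)
        normed = pp.normalize_log2_median(matrix)
        corrected = pp.remove_batch_effect(normed, meta)
        pcs, evr = pp.pca_embedding(corrected, n_components=2)
        io.write_protein_matrix(
            corrected, out / "corrected_matrix.tsv",
            provenance="normalized log2 median; batch=donor")
        _record(out / "corrected_matrix.tsv")
        report["stages"]["preprocess"] = {
            "n_proteins": int(matrix.values.shape[0]),
            "n_samples": int(matrix.values.shape[1]),
            "n_usable_protein_regions": int(mask.to_numpy().sum()),
            "pc_variance_shares": [float(v) for v in evr],
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'preprocess' failed: {exc}") from exc

    # --- stage: variability ------------------------------------------------
    try:
        cv = vb.protein_cv(matrix, meta)
        ds = vb.differential_stability(corrected, meta)
        th = cfg["thresholds"]
        report["stages"]["variability"] = {
            "median_v_inter": float(cv["v_inter"].median()),
            "frac_v_inter_below_.05": float((cv["v_inter"] < 0.05).mean()),
            "n_ds_high": int((ds > th["ds_high"]).sum()),
            "n_ds_low": int((ds < th["ds_low"]).sum()),
            "median_ds": float(ds.median()),
        }
        io.write_table(cv.reset_index(names="protein_id"),
                       out / "variability_cv.tsv")
        _record(out / "variability_cv.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage 'variability' failed: {exc}") from exc

    # --- stage: mrna coupling ---------------------------------------------
    if data.get("mrna") is not None and data.get("geom") is not None:
        try:
            prot_means = _left_region_means(corrected, meta)
            geom_l = data["geom"].hemisphere_subset("L")
            geom_l = dataclasses.replace(
                geom_l, labels=tuple(l.rsplit("_", 1)[0] for l in geom_l.labels))
            summary = vb.mrna_protein_coupling(
                prot_means, data["mrna"], geom_l,
                n_rot=cfg["spin"]["n_rot"], seed=cfg["seed"])
            io.write_table(summary.records, out / "mrna_coupling.tsv")
            _record(out / "mrna_coupling.tsv")
            report["stages"]["mrna_coupling"] = {
                "counts": summary.counts,
                "percentages": {k: round(v, 1)
                                for k, v in summary.percentages.items()},
            }
        except Exception as exc:
            raise RuntimeError(f"stage 'mrna_coupling' failed: {exc}") from exc

    # --- stage: differential expression ------------------------------------
    try:
        dep = de.dep_count_matrix(corrected, meta, test=cfg["de"]["test"],
                                  min_donors=min_donors)
        dep.counts.to_csv(out / "dep_counts.tsv", sep="\t", index_label="roi")
        _record(out / "dep_counts.tsv")
        counts_arr = dep.counts.to_numpy()
        iu = np.triu_indices(counts_arr.shape[0], k=1)
        report["stages"]["differential_expression"] = {
            "n_pairs": int(iu[0].size),
            "median_dep_count": float(np.median(counts_arr[iu])),
            "max_dep_count": int(counts_arr[iu].max()),
        }
    except Exception as exc:
        raise RuntimeError(
            f"stage 'differential_expression' failed: {exc}") from exc

    # --- stage: connectome -------------------------------------------------
    group = None
    sc_count = None
    if data.get("subjects"):
        try:
            fcs = [cn.subject_fc(ts) for ts in data["subjects"]]
            group = cn.group_fc(fcs, method=cfg["fc"]["aggregation"])
            io.write_connectivity(group, out / "group_fc.tsv")
            _record(out / "group_fc.tsv")
            homotopic, frac = cn.homotopic_summary(group)
            report["stages"]["connectome"] = {
                "n_subjects": len(fcs),
                "homotopic_argmax_fraction": float(frac),
                "mean_homotopic_r": float(homotopic.mean()),
            }
        except Exception as exc:
            raise RuntimeError(f"stage 'connectome' failed: {exc}") from exc
    if data.get("streamlines") is not None:
        sc_count = cn.streamline_count_matrix(data["streamlines"])
        density = cn.streamline_density(data["streamlines"])
        io.write_connectivity(density, out / "sc_density.tsv")
        _record(out / "sc_density.tsv")

    # --- stage: coupling ---------------------------------------------------
    if group is not None:
        try:
            res_fc = cp.coupling_correlation(dep, group)
            io.write_table(res_fc.per_pair, out / "coupling_fc_pairs.tsv")
            _record(out / "coupling_fc_pairs.tsv")
            block = {"fc": {"n_pairs": res_fc.n_pairs, "r": res_fc.r,
                            "p": res_fc.p}}
            if sc_count is not None:
                res_sc = cp.coupling_correlation(dep, sc_count)
                block["sc"] = {"n_pairs": res_sc.n_pairs, "r": res_sc.r,
                               "p": res_sc.p}
            sim = cp.profile_similarity(corrected, meta, hemisphere="L")
            clus = cp.hierarchical_clusters(sim, k=3)
            (out / "protein_dendrogram_left.nwk").write_text(
                clus.to_newick() + "\n")
            _record(out / "protein_dendrogram_left.nwk")
            block["profile_similarity_min_offdiag"] = float(
                sim.to_numpy()[np.triu_indices(len(sim), k=1)].min())
            report["stages"]["coupling"] = block
        except Exception as exc:
            raise RuntimeError(f"stage 'coupling' failed: {exc}") from exc

    # --- stage: ei_balance -------------------------------------------------
    if group is not None:
        try:
            sets = EIGeneSets(
                tuple(cfg.get("ei", {}).get("excitatory",
                                            EIGeneSets().excitatory)),
                tuple(cfg.get("ei", {}).get("inhibitory",
                                            EIGeneSets().inhibitory)))
            records = ei.ei_ratio(corrected, meta, sets)
            strengths = cn.node_strength(group,
                                         scope=cfg["fc"]["strength_scope"])
            r_l, p_l = ei.fc_ei_correlation(strengths, records, "L")
            r_r, p_r = ei.fc_ei_correlation(strengths, records, "R")
            ratios = records.set_index(["region", "hemisphere"])["ei_ratio"]
            order = [r for r in records["region"].unique()]
            cmp_ = ei.compare_fc_ei_dependence(
                strengths.loc[[f"{r}_L" for r in order]].to_numpy(),
                ratios.loc[[(r, "L") for r in order]].to_numpy(),
                strengths.loc[[f"{r}_R" for r in order]].to_numpy(),
                ratios.loc[[(r, "R") for r in order]].to_numpy())
            drivers = ei.gene_driver_profile(corrected, meta, strengths, sets)
            io.write_table(drivers, out / "ei_gene_drivers.tsv")
            _record(out / "ei_gene_drivers.tsv")
            report["stages"]["ei_balance"] = {
                "r_left": r_l, "p_left": p_l, "r_right": r_r, "p_right": p_r,
                "delta_z": cmp_.delta_z, "steiger_p": cmp_.p,
                "top_driver": (drivers["gene_id"].iloc[0]
                               if len(drivers) else None),
            }
        except Exception as exc:
            raise RuntimeError(f"stage 'ei_balance' failed: {exc}") from exc

    # --- stage: reorganisation ---------------------------------------------
    if data.get("cohort") is not None:
        try:
            cohort = data["cohort"]
            report["warnings"].extend(ro.validate_cohort(cohort))
            cmp_table = ro.roi_gmv_compare(cohort)
            io.write_table(cmp_table, out / "gmv_comparison.tsv")
            _record(out / "gmv_comparison.tsv")
            sig = cmp_table[cmp_table["q"] < cfg["thresholds"]["fdr_alpha"]]
            corr_table = ro.gmv_score_correlations(
                cohort, covariates=tuple(cfg["cohort"]["covariates"]))
            io.write_table(corr_table, out / "gmv_score_correlations.tsv")
            _record(out / "gmv_score_correlations.tsv")
            report["stages"]["reorganisation"] = {
                "n_rois_significant": int(len(sig)),
                "significant_rois": sig["roi"].tolist(),
                "n_partial_correlations": int(len(corr_table)),
            }
        except Exception as exc:
            raise RuntimeError(f"stage 'reorganisation' failed: {exc}") from exc

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, default=_json_default))
    return report


def _left_region_means(corrected, meta) -> pd.DataFrame:
    """Genes x 13-region mean log2 profile for the left hemisphere."""
    from .datatypes import REGIONS, group_labels

    sub = meta[meta["hemisphere"] == "L"]
    groups = group_labels(sub)
    out = {}
    for region in REGIONS:
        cols = [s for s in groups.index if groups[s] == f"{region}_L"]
        if cols:
            out[region] = corrected.values[cols].mean(axis=1, skipna=True)
    return pd.DataFrame(out)


def _json_default(obj: Any):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
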