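"""E/I ratio, FC-E/I correlations, Steiger comparison, gene drivers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from proteoconnect import connectome as cn
from proteoconnect import ei_balance as ei
from proteoconnect import preprocess as pp
from proteoconnect import synthetic_data as sd
from proteoconnect.datatypes import REGIONS
from proteoconnect.gene_sets import EIGeneSets


def _ratio_inputs(seed=0, **overrides):
    base = dict(n_proteins=60, n_donors=6, n_subjects=10, n_timepoints=120)
    base.update(overrides)
    cfg = sd.GeneratorConfig(seed=seed, **base)
    m, meta, gt = sd.generate_proteome(cfg)
    corrected = pp.remove_batch_effect(pp.normalize_log2_median(m), meta)
    return cfg, m, meta, gt, corrected


class TestEIRatio:
    def test_simple_ratio(self):
        cols = []
        data = {}
        for d in (1, 2):
            c = f"D{d:02d}_BA22_L"
            cols.append(c)
        # two excitatory genes summing to 4, one inhibitory at 2
        frame = pd.DataFrame(
            {c: [2.0, 2.0, 2.0] for c in cols},
            index=["GRIA1", "GRIN1", "GABRA1"])
        frame.loc["GABRA1"] = 2.0
        from proteoconnect.datatypes import ProteinMatrix

        meta = pd.DataFrame([{"sample_id": c, "donor": c.split("_")[0],
                              "region": "BA22", "hemisphere": "L"}
                             for c in cols])
        rec = ei.ei_ratio(ProteinMatrix(frame), meta)
        assert rec["ei_ratio"].iloc[0] == pytest.approx(2.0)

    def test_scale_invariance(self):
        _, m, meta, _, _ = _ratio_inputs(seed=1)
        from proteoconnect.datatypes import ProteinMatrix

        rec1 = ei.ei_ratio(m, meta)
        rec2 = ei.ei_ratio(ProteinMatrix(m.values * 2.0), meta)
        assert np.allclose(rec1["ei_ratio"], rec2["ei_ratio"])

    def test_planted_gradient_orders_ratios(self):
        """With the gradient planted on every excitatory gene the E/I
        ranking across regions tracks it (positively on the left,
        negatively on the right)."""
        from scipy.stats import spearmanr

        rhos_l, rhos_r = [], []
        for seed in range(5):
            _, _, meta, gt, corrected = _ratio_inputs(
                seed=seed, n_donors=10, ei_minor_scale=1.0)
            rec = ei.ei_ratio(corrected, meta)
            for hemi, store in (("L", rhos_l), ("R", rhos_r)):
                sub = rec[rec.hemisphere == hemi].set_index("region")
                ratios = sub.loc[list(REGIONS), "ei_ratio"].to_numpy()
                store.append(
                    spearmanr(ratios, gt.connectivity_gradient).statistic)
        assert np.mean(rhos_l) >= 0.9
        assert np.mean(rhos_r) <= -0.9

    def test_missing_inhibitory_errors(self):
        from proteoconnect.datatypes import ProteinMatrix

        frame = pd.DataFrame({"D01_BA22_L": [4.0]}, index=["GRIA1"])
        meta = pd.DataFrame([{"sample_id": "D01_BA22_L", "donor": "D01",
                              "region": "BA22", "hemisphere": "L"}])
        with pytest.raises(ValueError):
            ei.ei_ratio(ProteinMatrix(frame), meta)


class TestFcEiCorrelation:
    def test_proportional_gives_unity(self):
        records = pd.DataFrame({
            "region": list(REGIONS), "hemisphere": "L",
            "e_sum": np.arange(13, dtype=float) + 1,
            "i_sum": 1.0,
            "ei_ratio": np.arange(13, dtype=float) + 1,
        })
        strengths = pd.Series((np.arange(13) + 1) * 0.01,
                              index=[f"{r}_L" for r in REGIONS])
        r, p = ei.fc_ei_correlation(strengths, records, "L")
        assert r == pytest.approx(1.0)

    def test_constant_ratio_errors(self):
        records = pd.DataFrame({
            "region": list(REGIONS), "hemisphere": "L",
            "e_sum": 2.0, "i_sum": 1.0, "ei_ratio": 2.0,
        })
        strengths = pd.Series(np.linspace(0, 1, 13),
                              index=[f"{r}_L" for r in REGIONS])
        with pytest.raises(ValueError):
            ei.fc_ei_correlation(strengths, records, "L")

    def test_opposite_hemisphere_slopes_recovered(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = sd.GeneratorConfig(seed=seed, n_proteins=60, n_donors=10,
                                     n_subjects=16, n_timepoints=150)
            m, meta, gt = sd.generate_proteome(cfg)
            sim = sd.similarity_from_groundtruth(gt)
            subs, _ = sd.generate_connectome(cfg, sim, gt)
            group = cn.group_fc([cn.subject_fc(ts) for ts in subs])
            strengths = cn.node_strength(group)
            corrected = pp.remove_batch_effect(
                pp.normalize_log2_median(m), meta)
            rec = ei.ei_ratio(corrected, meta)
            r_l, _ = ei.fc_ei_correlation(strengths, rec, "L")
            r_r, _ = ei.fc_ei_correlation(strengths, rec, "R")
            hits += (r_l > 0 and r_r < 0)
        assert hits / n_seeds >= 0.95


class TestCompareCorrelations:
    def test_equal_correlations_null(self):
        cmp_ = ei.compare_correlations(0.4, 0.4, n=13)
        assert cmp_.delta_z == 0.0
        assert cmp_.statistic == 0.0
        assert cmp_.p == pytest.approx(1.0)

    def test_independent_fallback_closed_form(self):
        cmp_ = ei.compare_correlations(0.5, -0.5, n=13)
        expected = (np.arctanh(0.5) - np.arctanh(-0.5)) / np.sqrt(2 / 10)
        assert cmp_.statistic == pytest.approx(expected, abs=1e-12)
        assert cmp_.method == "fisher-independent"

    def test_antisymmetry(self):
        cross = (0.5, 0.2, 0.1, 0.6)
        a = ei.compare_correlations(0.6, -0.3, 13, cross_corrs=cross)
        # swapping left/right also swaps the cross-correlation roles:
        # (r13, r14, r23, r24) -> (r31, r32, r41, r42)
        swapped = (cross[0], cross[2], cross[1], cross[3])
        b = ei.compare_correlations(-0.3, 0.6, 13, cross_corrs=swapped)
        assert b.delta_z == pytest.approx(-a.delta_z)
        assert b.statistic == pytest.approx(-a.statistic)
        assert b.p == pytest.approx(a.p)

    def test_degenerate_r_rejected(self):
        with pytest.raises(ValueError):
            ei.compare_correlations(1.0, 0.0, 13)
        with pytest.raises(ValueError):
            ei.compare_correlations(0.5, 0.0, 3)

    def test_dependent_null_calibrated(self):
        """Type-I error of the Steiger dependent comparison stays near the
        nominal .05 under a matched-pairs null (smaller replicate count
        here; the full calibration runs in the acceptance suite)."""
        rng = np.random.default_rng(17)
        R = np.array([
            [1.0, 0.3, 0.5, 0.15],
            [0.3, 1.0, 0.15, 0.5],
            [0.5, 0.15, 1.0, 0.3],
            [0.15, 0.5, 0.3, 1.0]])
        L = np.linalg.cholesky(R)
        rej = 0
        n_rep = 500
        for _ in range(n_rep):
            z = rng.normal(size=(13, 4)) @ L.T
            cmp_ = ei.compare_fc_ei_dependence(z[:, 0], z[:, 1],
                                               z[:, 2], z[:, 3])
            rej += (cmp_.p <= 0.05)
        assert 0.02 <= rej / n_rep <= 0.08


class TestGeneDrivers:
    def test_single_planted_driver_ranks_first(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = sd.GeneratorConfig(seed=seed, n_proteins=60, n_donors=10,
                                     n_subjects=16, n_timepoints=150,
                                     ei_driver_genes=("GRIA4",),
                                     ei_minor_scale=0.0)
            m, meta, gt = sd.generate_proteome(cfg)
            sim = sd.similarity_from_groundtruth(gt)
            subs, _ = sd.generate_connectome(cfg, sim, gt)
            group = cn.group_fc([cn.subject_fc(ts) for ts in subs])
            strengths = cn.node_strength(group)
            corrected = pp.remove_batch_effect(
                pp.normalize_log2_median(m), meta)
            table = ei.gene_driver_profile(corrected, meta, strengths)
            hits += (table["gene_id"].iloc[0] == "GRIA4")
        assert hits / n_seeds >= 0.9

    def test_single_gene_set_leave_one_out_errors(self):
        _, _, meta, _, corrected = _ratio_inputs(seed=3)
        strengths = pd.Series(np.linspace(0.1, 0.5, 26),
                              index=[f"{r}_{h}" for h in ("L", "R")
                                     for r in REGIONS])
        sets = EIGeneSets(excitatory=("GRIA1",), inhibitory=("GABRA1",))
        with pytest.raises(ValueError, match="single detected gene"):
            ei.gene_driver_profile(corrected, meta, strengths, sets)

    def test_null_ranks_approximately_uniform(self):
        """With no lateralised planting all excitatory genes are
        exchangeable: the top-driver identity should not concentrate
        (chi-square goodness of fit not rejected at alpha = .01)."""
        from scipy.stats import chisquare

        sets = EIGeneSets()
        counts = {g: 0 for g in sets.excitatory + sets.inhibitory}
        n_seeds = 57  # 3 per cell over the 19 exchangeable genes
        for seed in range(n_seeds):
            cfg = sd.GeneratorConfig(seed=seed, n_proteins=60, n_donors=6,
                                     n_subjects=6, n_timepoints=100,
                                     ei_slope_left=0.0, ei_slope_right=0.0)
            m, meta, gt = sd.generate_proteome(cfg)
            sim = sd.similarity_from_groundtruth(gt)
            subs, _ = sd.generate_connectome(cfg, sim, gt)
            group = cn.group_fc([cn.subject_fc(ts) for ts in subs])
            strengths = cn.node_strength(group)
            corrected = pp.remove_batch_effect(
                pp.normalize_log2_median(m), meta)
            table = ei.gene_driver_profile(corrected, meta, strengths)
            counts[table["gene_id"].iloc[0]] += 1
        stat, p = chisquare(list(counts.values()))
        assert p > 0.01
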