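"""CV / V_inter, differential stability, spin test and coupling classes."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from proteoconnect import synthetic_data as sd
from proteoconnect import variability as vb
from proteoconnect.datatypes import ProteinMatrix, REGIONS
from proteoconnect.variability import (
    _greedy_assignment,
    classify_concordance,
    mrna_protein_coupling,
    spin_test,
)


def _meta_for(columns):
    rows = []
    for c in columns:
        donor, region, hemi = c.split("_")
        rows.append({"sample_id": c, "donor": donor, "region": region,
                     "hemisphere": hemi})
    return pd.DataFrame(rows)


class TestProteinCV:
    def test_identical_values_give_zero_cv(self):
        cols = [f"D{i:02d}_BA22_L" for i in range(1, 5)]
        vals = pd.DataFrame({c: [3.0, 8.0] for c in cols})
        table = vb.protein_cv(ProteinMatrix(vals), _meta_for(cols))
        assert np.allclose(table["cv_BA22_L"], 0.0)

    def test_closed_form_small_sample(self):
        # donors {1, 2, 3}: sample SD 1, mean 2 -> CV 0.5
        cols = [f"D{i:02d}_BA21_L" for i in range(1, 4)]
        vals = pd.DataFrame([[1.0, 2.0, 3.0]], columns=cols)
        table = vb.protein_cv(ProteinMatrix(vals), _meta_for(cols))
        assert table["cv_BA21_L"].iloc[0] == pytest.approx(0.5)

    def test_region_with_single_detection_excluded(self):
        cols = [f"D{i:02d}_BA22_L" for i in range(1, 4)] + ["D01_BA21_L"]
        vals = pd.DataFrame([[2.0, 3.0, 4.0, 5.0]], columns=cols)
        table = vb.protein_cv(ProteinMatrix(vals), _meta_for(cols))
        assert np.isnan(table["cv_BA21_L"].iloc[0])
        assert table["v_inter"].iloc[0] == table["cv_BA22_L"].iloc[0]

    def test_median_v_inter_matches_lognormal_oracle(self):
        """With pure log-normal noise, the CV tends to sqrt(exp(s^2) - 1)
        where s = noise_sd * ln 2; checked against a direct large-n
        simulation of the same quantity."""
        cfg = sd.GeneratorConfig(seed=8, n_proteins=600, n_donors=10,
                                 missing_rate=0.0, region_effect_frac=0.0001,
                                 region_effect_sd=0.0, donor_offset_sd=0.0,
                                 donor_offset_jitter=0.0,
                                 hemisphere_effect_sd=0.0,
                                 ei_slope_left=0.0, ei_slope_right=0.0)
        m, meta, _ = sd.generate_proteome(cfg)
        table = vb.protein_cv(m, meta)
        s = cfg.noise_sd * np.log(2.0)
        # oracle: simulate sample CV of lognormal draws at n=10
        rng = np.random.default_rng(0)
        draws = np.exp(s * rng.normal(size=(20000, cfg.n_donors)))
        cv_oracle = np.median(draws.std(axis=1, ddof=1) / draws.mean(axis=1))
        assert abs(table["v_inter"].median() - cv_oracle) < 0.02
        # the small-sample median CV sits slightly below the asymptotic
        # lognormal value sqrt(exp(s^2) - 1) (downward bias at n = 10)
        assert abs(cv_oracle - np.sqrt(np.exp(s ** 2) - 1)) < 0.04


class TestDifferentialStability:
    def test_shared_profile_gives_one(self):
        cols = [f"D{i:02d}_{r}_L" for i in range(1, 4) for r in
                ("BA22", "BA21", "BA44", "BA45")]
        base = {"BA22": 1.0, "BA21": 2.0, "BA44": 4.0, "BA45": 3.0}
        vals = pd.DataFrame(
            {c: [base[c.split("_")[1]]] * 2 for c in cols})
        ds = vb.differential_stability(ProteinMatrix(vals), _meta_for(cols))
        assert np.allclose(ds, 1.0)

    def test_opposite_profiles_give_minus_one(self):
        regions = ("BA22", "BA21", "BA44")
        cols = [f"D{i:02d}_{r}_L" for i in (1, 2) for r in regions]
        prof = {"D01": [1.0, 2.0, 3.0], "D02": [3.0, 2.0, 1.0]}
        data = {}
        for c in cols:
            donor, region, _ = c.split("_")
            data[c] = [prof[donor][regions.index(region)]]
        ds = vb.differential_stability(ProteinMatrix(pd.DataFrame(data)),
                                       _meta_for(cols))
        assert ds.iloc[0] == pytest.approx(-1.0)

    def test_independent_profiles_centred_on_zero(self):
        cfg = sd.GeneratorConfig(seed=9, n_proteins=500, n_donors=6,
                                 missing_rate=0.0, region_effect_frac=0.0001,
                                 region_effect_sd=0.0, donor_offset_sd=0.0,
                                 donor_offset_jitter=0.0,
                                 ei_slope_left=0.0, ei_slope_right=0.0)
        m, meta, _ = sd.generate_proteome(cfg)
        ds = vb.differential_stability(m, meta)
        # null DS has mean 0; SE of the median over 500 proteins
        assert abs(ds.median()) < 3 * (1 / np.sqrt(12)) / np.sqrt(len(ds))

    def test_affine_rescaling_invariance(self, proteome):
        m, meta, _ = proteome
        ds1 = vb.differential_stability(m, meta)
        vals = m.values.copy()
        for d, scale in (("D01", 3.0), ("D02", 0.5)):
            cols = meta[meta.donor == d]["sample_id"]
            vals[cols] = vals[cols] * scale
        ds2 = vb.differential_stability(ProteinMatrix(vals), meta)
        pd.testing.assert_series_equal(ds1, ds2, atol=1e-12, rtol=0)


class TestSpinTest:
    def test_identical_maps_give_rho_one_and_p_floor(self, left_geometry):
        rng = np.random.default_rng(0)
        x = rng.normal(size=13)
        rho, p = spin_test(x, x, left_geometry, n_rot=99, seed=1)
        assert rho == pytest.approx(1.0)
        assert p >= 1 / 100

    def test_identity_rotation_reproduces_observed(self, left_geometry):
        """A zero-angle rotation must assign every ROI to itself, so the
        corresponding null draw equals the observed statistic."""
        coords = left_geometry.coords
        arc = np.arccos(np.clip(coords @ coords.T, -1, 1))
        perm = _greedy_assignment(arc)
        assert np.array_equal(perm, np.arange(13))

    def test_duplicate_coordinates_rejected(self, left_geometry):
        geom = dataclasses.replace(
            left_geometry,
            coords=np.vstack([left_geometry.coords[:-1],
                              left_geometry.coords[[0]]]))
        with pytest.raises(ValueError, match="duplicate"):
            spin_test(np.arange(13.0), np.arange(13.0), geom, n_rot=99,
                      seed=0)

    def test_permutation_null_fallback(self, left_geometry):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=13), rng.normal(size=13)
        rho, p = spin_test(x, y, left_geometry, n_rot=199, seed=5,
                           null="permute")
        assert -1 <= rho <= 1 and 0 < p <= 1

    def test_mirrored_hemispheres_spin_together(self):
        geom = sd.generate_roi_geometry(13, seed=4)
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=26), rng.normal(size=26)
        perms = vb.spin_permutations(geom, n_rot=50, seed=2)
        # permutations stay within hemisphere
        assert np.all(perms[:, :13] < 13) and np.all(perms[:, 13:] >= 13)
        rho, p = spin_test(x, y, geom, n_rot=99, seed=3)
        assert 0 < p <= 1


class TestConcordanceClasses:
    @pytest.mark.parametrize("rho,q,expected", [
        (0.91, 0.01, "Concordant"),
        (-0.57, 0.01, "Discordant"),
        (0.40, 0.001, "Uncoupled"),
        (0.60, 0.10, "Uncoupled"),
        (-0.19, 0.001, "Uncoupled"),
        (float("nan"), 0.001, "Uncoupled"),
    ])
    def test_threshold_logic(self, rho, q, expected):
        assert classify_concordance(rho, q) == expected

    def test_identical_tables_give_rho_one(self, left_geometry):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(rng.normal(size=(20, 13)),
                             index=[f"G{i}" for i in range(20)],
                             columns=list(REGIONS))
        summary = mrna_protein_coupling(table, table, left_geometry,
                                        n_rot=99, seed=0)
        assert np.allclose(summary.records["rho"], 1.0)

    def test_class_percentages_sum_to_100(self, left_geometry):
        rng = np.random.default_rng(2)
        a = pd.DataFrame(rng.normal(size=(50, 13)),
                         index=[f"G{i}" for i in range(50)],
                         columns=list(REGIONS))
        b = pd.DataFrame(rng.normal(size=(50, 13)), index=a.index,
                         columns=list(REGIONS))
        summary = mrna_protein_coupling(a, b, left_geometry, n_rot=99, seed=0)
        assert sum(summary.percentages.values()) == pytest.approx(100.0)

    def test_planted_classes_recovered(self, left_geometry):
        """Strongly coupled/anticoupled genes are classified correctly in
        >= 90% of cases; null genes stay overwhelmingly Uncoupled.

        Planted couplings of |rho| = .95 are used: with 13 regions the
        two-sided spatial-permutation null has SD ~ 1/sqrt(12), which sets
        the detection limit (weaker couplings are not reliably separable).
        """
        rates_c, rates_d, rates_fp = [], [], []
        for seed in range(2):
            cfg = sd.GeneratorConfig(seed=seed, n_proteins=400, n_donors=10)
            m, meta, _ = sd.generate_proteome(cfg)
            genes = list(m.protein_ids)
            rng = np.random.default_rng(50 + seed)
            chosen = rng.choice(len(genes), size=120, replace=False)
            rho_map = {genes[g]: (0.95 if k < 40 else -0.95)
                       for k, g in enumerate(chosen)}
            mrna = sd.generate_mrna(m, meta, rho_map, cfg)
            from proteoconnect.pipeline import _left_region_means
            from proteoconnect.preprocess import (normalize_log2_median,
                                                  remove_batch_effect)

            corr = remove_batch_effect(normalize_log2_median(m), meta)
            summary = mrna_protein_coupling(_left_region_means(corr, meta),
                                            mrna, left_geometry, n_rot=499,
                                            seed=seed)
            rec = summary.records.set_index("gene_id")
            conc = [genes[g] for k, g in enumerate(chosen) if k < 40]
            disc = [genes[g] for k, g in enumerate(chosen) if k >= 40]
            rates_c.append(
                (rec.loc[conc, "coupling_class"] == "Concordant").mean())
            rates_d.append(
                (rec.loc[disc, "coupling_class"] == "Discordant").mean())
            null_genes = rec.drop(index=conc + disc)
            rates_fp.append(
                (null_genes["coupling_class"] != "Uncoupled").mean())
        assert np.mean(rates_c) >= 0.9
        assert np.mean(rates_d) >= 0.9
        assert np.mean(rates_fp) <= 0.05
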