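"""Generator contracts: determinism, planted structure, truth consistency."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sarcospot as ss


class TestBulkCohort:
    def test_determinism(self):
        m1, t1 = ss.gen_bulk_cohort(n_genes=500, seed=3)
        m2, t2 = ss.gen_bulk_cohort(n_genes=500, seed=3)
        assert m1.values.equals(m2.values)
        assert t1.planted_up_genes == t2.planted_up_genes

    def test_truth_sets_sized_and_disjoint(self):
        _, truth = ss.gen_bulk_cohort(n_genes=1000, n_up=50, n_down=20, seed=0)
        assert len(truth.planted_up_genes) == 50
        assert len(truth.planted_down_genes) == 20
        assert not truth.planted_up_genes & truth.planted_down_genes

    def test_zero_effect_indistinguishable(self):
        """At effect 0 planted and null genes pass a two-sample t-test as
        exchangeable in >= 98% of genes."""
        sig = 0
        total = 0
        for seed in range(4):
            m, truth = ss.gen_bulk_cohort(
                n_genes=600, n_up=100, n_down=0, effect_log2fc=0.0, seed=seed
            )
            log2 = m.log2()
            planted = sorted(truth.planted_up_genes)
            t_cols = m.group_columns("tumor")
            n_cols = m.group_columns("normal")
            p = stats.ttest_ind(
                log2.loc[planted, t_cols], log2.loc[planted, n_cols], axis=1
            ).pvalue
            sig += (p < 0.01).sum()
            total += len(p)
        assert 1 - sig / total >= 0.98

    def test_low_expression_fraction_below_qc_floor(self):
        m, _ = ss.gen_bulk_cohort(n_genes=2000, seed=1, low_expr_frac=0.3)
        below = ((m.values >= 1).mean(axis=1) < 0.2).mean()
        assert 0.2 < below < 0.4

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            ss.gen_bulk_cohort(n_genes=10, n_up=8, n_down=5)
        with pytest.raises(ValueError):
            ss.gen_bulk_cohort(n_tumor=1)
        with pytest.raises(ValueError):
            ss.gen_bulk_cohort(effect_log2fc=-1.0)


class TestCelllinePanel:
    def test_high_genes_reach_top_percentiles(self):
        genes = [f"G{i:05d}" for i in range(500)]
        high = set(genes[:25])
        m = ss.gen_cellline_panel(500, 4, high, seed=0, gene_ids=genes)
        pct = ss.compute_cell_percentiles(m, genes)
        assert pct[sorted(high)].mean() > 0.9

    def test_no_high_genes_percentiles_uniform(self):
        # within a single sample the percentiles are exactly the rank grid,
        # so they pass a KS test against the uniform
        m = ss.gen_cellline_panel(800, 1, None, seed=1)
        pct = ss.compute_cell_percentiles(m, list(m.gene_ids))
        assert stats.kstest(pct, "uniform").pvalue > 0.01

    def test_determinism_and_unknown_genes(self):
        a = ss.gen_cellline_panel(100, 2, seed=5)
        b = ss.gen_cellline_panel(100, 2, seed=5)
        assert a.values.equals(b.values)
        with pytest.raises(KeyError):
            ss.gen_cellline_panel(100, 2, {"nope"}, seed=0)


class TestSpatialTissue:
    def test_determinism(self):
        a1, _ = ss.gen_spatial_tissue(n_cells=300, seed=4)
        a2, _ = ss.gen_spatial_tissue(n_cells=300, seed=4)
        assert np.array_equal(np.asarray(a1.X), np.asarray(a2.X))
        assert a1.obs.equals(a2.obs)

    def test_neutral_ratio_one(self):
        clones = [ss.CloneSpec("a", 0.5, [("chr1", 0, 100, 1.0)]),
                  ss.CloneSpec("b", 0.5, [])]
        adata, truth = ss.gen_spatial_tissue(
            n_cells=2000, clones=clones, seed=0, n_marker_genes=0
        )
        X = np.asarray(adata.X, float)
        in_a = (truth.clone_of_cell == "a").to_numpy()
        seg = np.arange(100)
        ratio = X[in_a][:, seg].mean() / X[~in_a & truth.clone_of_cell.notna().to_numpy()][:, seg].mean()
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_planted_copy_ratio_scales_counts(self):
        clones = [ss.CloneSpec("neutral", 0.5, []),
                  ss.CloneSpec("gain", 0.5, [("chr1", 50, 150, 1.5)])]
        adata, truth = ss.gen_spatial_tissue(
            n_cells=2500, clones=clones, seed=1, n_marker_genes=0,
            doublet_frac=0.0, low_quality_frac=0.0,
        )
        X = np.asarray(adata.X, float)
        depth = X.sum(axis=1, keepdims=True)
        norm = X / depth
        gain = (truth.clone_of_cell == "gain").to_numpy()
        neut = (truth.clone_of_cell == "neutral").to_numpy()
        seg = np.arange(50, 150)
        ratio = norm[gain][:, seg].mean() / norm[neut][:, seg].mean()
        assert ratio == pytest.approx(1.5, rel=0.1)

    def test_immune_fraction_and_intensity(self):
        adata, truth = ss.gen_spatial_tissue(n_cells=5000, immune_frac=0.1, seed=2)
        n_immune = len(truth.immune_cells)
        assert abs(n_immune - 500) < 4 * np.sqrt(500)
        imm = adata.obs.index.isin(truth.immune_cells)
        assert adata.obs.loc[imm, "cd45_intensity"].min() > \
            adata.obs.loc[~imm, "cd45_intensity"].median()

    def test_low_quality_cells_below_feature_floor(self):
        adata, _ = ss.gen_spatial_tissue(n_cells=1000, seed=3, low_quality_frac=0.05)
        from sarcospot.spatial import n_features
        assert (n_features(adata) < 20).sum() >= 40

    def test_segment_outside_panel_rejected(self):
        bad = [ss.CloneSpec("x", 1.0, [("chr1", 400, 600, 1.5)])]
        with pytest.raises(ValueError, match="outside"):
            ss.gen_spatial_tissue(n_cells=100, clones=bad, seed=0)

    def test_clones_spatially_coherent(self):
        adata, truth = ss.gen_spatial_tissue(n_cells=2000, seed=6)
        obs = adata.obs
        for clone in ("neutral", "aberrant"):
            cells = truth.clone_of_cell == clone
            for fov in range(4):
                sub = obs[cells.to_numpy() & (obs["fov"] == fov).to_numpy()]
                if len(sub) < 10:
                    continue
                spread = sub[["x_slide_mm", "y_slide_mm"]].std().max()
                assert spread < 0.1  # concentrated blob inside a 0.5 mm FOV


class TestClinicalCohort:
    def test_rows_and_columns_populated(self):
        t = ss.gen_clinical_cohort(30, seed=0)
        assert len(t) == 30
        assert t.notna().all().all()
        assert set(t["survival"]) == {"Alive", "DOD"}

    def test_h_score_consistent_with_fractions(self):
        t = ss.gen_clinical_cohort(30, seed=1)
        for _, row in t.iterrows():
            fr = [row[f"frac_intensity{i}"] for i in range(4)]
            assert ss.compute_h_score(fr) == pytest.approx(row["h_score"])
            assert row["positivity_pct"] == pytest.approx(100 * (1 - fr[0]))
        assert t["h_score"].between(0, 300).all()

    def test_determinism_and_min_n(self):
        assert ss.gen_clinical_cohort(12, seed=7).equals(
            ss.gen_clinical_cohort(12, seed=7)
        )
        with pytest.raises(ValueError):
            ss.gen_clinical_cohort(3)

    def test_null_effect_type_i_calibration(self):
        """Wilcoxon on positivity by survival group under effect=0 rejects
        at about (or conservatively below) the nominal 5% over 500 seeds."""
        rej = 0
        n_seeds = 500
        for seed in range(n_seeds):
            t = ss.gen_clinical_cohort(30, effect=0.0, seed=seed)
            _, p = ss.compare_groups_wilcoxon(
                t["positivity_pct"].to_numpy(), t["survival"].to_numpy()
            )
            rej += p < 0.05
        assert rej / n_seeds <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_seeds)
        assert rej / n_seeds >= 0.005
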