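"""Generators: bookkeeping, determinism, and ground-truth fidelity."""

import numpy as np
import pandas as pd
import pytest

from ovotox import simdata
from ovotox.errors import ValidationError


class TestAtlas:
    def test_bookkeeping_counts(self):
        spec = [
            simdata.ClusterSpec("c1", "germ", 100),
            simdata.ClusterSpec("c2", "granulosa", 100),
            simdata.ClusterSpec("c3", "theca", 100),
        ]
        sc, meta, truth = simdata.generate_atlas(
            n_genes=200, clusters_spec=spec, n_subjects=2, seed=1, qc_fail_frac=0.05
        )
        assert len(meta) == 300 + len(truth.qc_fail_cells)
        assert len(truth.qc_fail_cells) == 15
        assert sc.shape == (len(meta), 200)

    def test_theta_columns_sum_to_one(self, atlas_data):
        _, _, truth = atlas_data
        np.testing.assert_allclose(truth.theta.sum(axis=0), 1.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_markers_elevated_in_own_cluster(self, seed):
        sc, meta, truth = simdata.generate_atlas(seed=seed)
        df = sc.to_frame()
        meta = meta.set_index("cell_id")
        normal = ~meta.index.isin(truth.qc_fail_cells)
        for cluster, markers in truth.markers.items():
            in_k = normal & (meta["cluster_id"] == cluster)
            # compare library-normalized means so cell size cancels
            rel = df.div(df.sum(axis=1), axis=0)
            for g in markers:
                assert rel.loc[in_k, g].mean() > rel.loc[normal & ~in_k, g].mean()

    def test_same_seed_identical(self):
        a = simdata.generate_atlas(seed=5)
        b = simdata.generate_atlas(seed=5)
        assert np.array_equal(a[0].values, b[0].values)
        assert a[1].equals(b[1])

    def test_single_subject_rejected(self):
        with pytest.raises(ValidationError, match="2 subjects"):
            simdata.generate_atlas(n_subjects=1)


class TestBulkCohort:
    def test_design_dimensions(self, atlas_data):
        _, _, truth = atlas_data
        design = simdata.DesignSpec(compounds=("DES",), n_replicates=6)
        bulk, meta, _ = simdata.generate_bulk_cohort(truth, design, seed=1)
        # 3 stages x (control + 3 doses) x 6 replicates
        assert bulk.shape[1] == 72
        assert len(meta) == 72

    def test_noiseless_column_equals_mixture_expectation(self, atlas_data):
        _, _, truth = atlas_data
        design = simdata.DesignSpec(compounds=("DES",), dose_levels=(), n_replicates=2,
                                    stages=("PND6",))
        bulk, meta, ctruth = simdata.generate_bulk_cohort(
            truth, design, seed=2, dispersion=None, proportion_concentration=1e9
        )
        sid = meta["sample_id"].iloc[0]
        expected = simdata.mixture_expectation(
            truth, ctruth.proportions.loc[sid]
        )
        np.testing.assert_allclose(
            ctruth.expected[sid].to_numpy(), expected.to_numpy(), atol=1e-12
        )
        # counts are the rounded expectation at the library size
        np.testing.assert_allclose(
            bulk.to_frame()[sid].to_numpy(),
            np.rint(expected.to_numpy() * ctruth.lib_sizes[sid]),
        )

    def test_planted_fold_change_realized(self, atlas_data):
        """log2FC = 1 planted on an expressed gene doubles its mean counts."""
        _, _, truth = atlas_data
        expr = simdata.mixture_expectation(truth, simdata.stage_proportions(truth).loc["PND6"])
        gene = expr.idxmax()
        eff = [simdata.PlantedEffect(gene, "DES", 1.0, stage="PND6", dose_level="high")]
        design = simdata.DesignSpec(compounds=("DES",), dose_levels=("high",), stages=("PND6",),
                                    n_replicates=4)
        ratios = []
        for seed in range(20):
            bulk, meta, _ = simdata.generate_bulk_cohort(truth, design, eff, seed=seed)
            df = bulk.to_frame()
            exposed = meta.loc[meta["compound"] == "DES", "sample_id"]
            control = meta.loc[meta["compound"] == "control", "sample_id"]
            ratios.append(df.loc[gene, exposed].mean() / df.loc[gene, control].mean())
        assert abs(np.mean(ratios) - 2.0) < 0.2

    def test_effect_on_unknown_gene_rejected(self, atlas_data):
        _, _, truth = atlas_data
        with pytest.raises(ValidationError, match="absent"):
            simdata.generate_bulk_cohort(
                truth, effects_spec=[simdata.PlantedEffect("nope", "DES", 1.0)]
            )

    def test_proportions_rows_sum_to_one(self, cohort):
        _, _, ctruth = cohort
        np.testing.assert_allclose(ctruth.proportions.sum(axis=1), 1.0, atol=1e-9)

    def test_germ_cells_decline_across_stages(self, atlas_data):
        _, _, truth = atlas_data
        targets = simdata.stage_proportions(truth)
        germ = [c for c, b in truth.cluster_broad.items() if b == "germ"]
        series = targets[germ].sum(axis=1)
        assert series["PND6"] > series["PND14"] > series["PND22"]
        assert (series["PND22"] - series["PND6"]) / series["PND6"] < -0.5


class TestOrthologMap:
    def test_all_one2one(self):
        genes = [f"g{i}" for i in range(20)]
        omap, one2one = simdata.generate_ortholog_map(genes, 1.0, 0.0, seed=1)
        assert sorted(one2one) == sorted(genes)
        assert set(omap["relationship"]) == {"one2one"}

    def test_all_one2many_gives_empty_one2one(self):
        genes = [f"g{i}" for i in range(20)]
        omap, one2one = simdata.generate_ortholog_map(genes, 0.0, 1.0, seed=1)
        assert one2one == []
        assert set(omap["relationship"]) == {"one2many"}

    @pytest.mark.parametrize("f11,f1m", [(0.5, 0.3), (0.8, 0.1), (0.0, 0.5)])
    def test_labels_match_recounted_multiplicities(self, f11, f1m):
        genes = [f"g{i}" for i in range(50)]
        omap, _ = simdata.generate_ortholog_map(genes, f11, f1m, seed=2)
        src_counts = omap["source_gene"].value_counts()
        tgt_counts = omap["target_gene"].value_counts()
        for _, row in omap.iterrows():
            ns, nt = src_counts[row["source_gene"]], tgt_counts[row["target_gene"]]
            if row["relationship"] == "one2one":
                assert (ns, nt) == (1, 1)
            elif row["relationship"] == "one2many":
                assert ns > 1 and nt == 1

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValidationError):
            simdata.generate_ortholog_map([], 1.0, 0.0)


class TestGeneSets:
    def test_counts_and_determinism(self):
        genes = [f"g{i}" for i in range(100)]
        gsc1, _ = simdata.generate_gene_sets(genes, n_terms=10, seed=3)
        gsc2, _ = simdata.generate_gene_sets(genes, n_terms=10, seed=3)
        assert len(gsc1) == 10
        assert all(gsc1[t] for t in gsc1)
        assert gsc1.sets == gsc2.sets

    def test_enriched_terms_draw_from_target(self):
        genes = [f"g{i}" for i in range(200)]
        target = genes[:30]
        gsc, truth = simdata.generate_gene_sets(
            genes, n_terms=5, enriched_spec={"T_HIT": target}, seed=4, frac_from_target=0.6
        )
        overlap = len(gsc["T_HIT"] & set(target))
        assert overlap >= 0.5 * len(gsc["T_HIT"])
        assert set(truth["T_HIT"]) == gsc["T_HIT"] & set(target)

    def test_oversized_term_rejected(self):
        with pytest.raises(ValidationError, match="exceeds"):
            simdata.generate_gene_sets([f"g{i}" for i in range(5)], term_size_range=(10, 20))
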