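"""Deconvolution: solver, ortholog restriction, proportions, comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ovotox import simdata
from ovotox.atlas import ReferenceSignature
from ovotox.deconv import (
    CellTypeDeconvolver,
    aggregate_broad_types,
    compare_proportions,
    deconvolve_sample,
    nnls,
    restrict_orthologs,
    weighted_nnls_proportions,
)
from ovotox.errors import UnderdeterminedError, ValidationError
from ovotox.io import CountMatrix
from ovotox.stats import rank_sum_test


def _truth_reference(truth, tau2=0.0):
    return ReferenceSignature(
        truth.theta, truth.theta * 0.0 + tau2, truth.cell_size, truth.cluster_broad
    )


class TestNnls:
    def test_noiseless_recovery(self, rng):
        a = rng.normal(size=(12, 3)) ** 2
        beta_true = np.array([0.5, 0.0, 2.0])
        beta = nnls(a, a @ beta_true)
        np.testing.assert_allclose(beta, beta_true, atol=1e-8)

    def test_negative_component_clipped(self):
        beta = nnls(np.eye(2), np.array([3.0, -1.0]))
        np.testing.assert_allclose(beta, [3.0, 0.0])

    def test_objective_beats_dense_grid(self, rng):
        """On random 10x3 problems the solution beats every grid point."""
        for _ in range(5):
            a = np.abs(rng.normal(size=(10, 3)))
            b = a @ rng.uniform(0, 1, size=3) + rng.normal(0, 0.05, size=10)
            beta = nnls(a, b)
            obj = np.sum((a @ beta - b) ** 2)
            grid = np.arange(0.0, 1.0001, 0.05)
            best = min(
                np.sum((a @ np.array(g) - b) ** 2)
                for g in itertools.product(grid, repeat=3)
            )
            assert obj <= best + 1e-12

    def test_zero_column_rejected(self):
        a = np.array([[1.0, 0.0], [2.0, 0.0]])
        with pytest.raises(ValidationError, match="index 1"):
            nnls(a, np.array([1.0, 1.0]))


class TestRestrictOrthologs:
    def _bundle(self, truth):
        omap, one2one = simdata.generate_ortholog_map(
            list(truth.theta.index), 1.0, 0.0, seed=1
        )
        rename = dict(zip(omap["source_gene"], omap["target_gene"]))
        bulk, meta, ct = simdata.generate_bulk_cohort(truth, seed=2, rename=rename)
        return omap, bulk, meta, ct

    def test_all_one2one_keeps_all_common_genes(self, atlas_data):
        _, _, truth = atlas_data
        omap, bulk, _, _ = self._bundle(truth)
        ref = _truth_reference(truth)
        theta, tau2, bulk_df, col_mass = restrict_orthologs(ref, bulk, omap)
        assert len(theta.index) == len(truth.theta.index)
        np.testing.assert_allclose(theta.sum(axis=0), 1.0, atol=1e-9)
        # nothing dropped -> full expression mass captured
        np.testing.assert_allclose(col_mass, 1.0, atol=1e-9)

    def test_one2many_source_excluded(self, atlas_data):
        _, _, truth = atlas_data
        omap, bulk, _, _ = self._bundle(truth)
        victim = omap["source_gene"].iloc[0]
        omap = omap.copy()
        omap.loc[omap["source_gene"] == victim, "relationship"] = "one2many"
        extra = pd.DataFrame(
            {"source_gene": [victim], "target_gene": ["Rextra"], "relationship": ["one2many"]}
        )
        omap = pd.concat([omap, extra], ignore_index=True)
        theta, _, _, _ = restrict_orthologs(_truth_reference(truth), bulk, omap)
        assert victim not in theta.index

    def test_empty_intersection_is_underdetermined(self, atlas_data):
        _, _, truth = atlas_data
        omap, bulk, _, _ = self._bundle(truth)
        foreign = CountMatrix(
            bulk.values, [f"other{i}" for i in range(len(bulk.row_ids))], bulk.col_ids
        )
        with pytest.raises(UnderdeterminedError):
            restrict_orthologs(_truth_reference(truth), foreign, omap)


class TestDeconvolveSample:
    def test_noiseless_exact_recovery(self, atlas_data):
        _, _, truth = atlas_data
        clusters = list(truth.theta.columns)
        p_true = pd.Series(
            np.linspace(1, 2, len(clusters)) / np.linspace(1, 2, len(clusters)).sum(),
            index=clusters,
        )
        x = simdata.mixture_expectation(truth, p_true)
        res = deconvolve_sample(
            x.to_numpy(), truth.theta, truth.theta * 0.0, truth.cell_size, truth.cluster_broad
        )
        np.testing.assert_allclose(res.proportions, p_true, atol=1e-6)
        assert res.converged

    def test_zero_tau_equals_single_plain_nnls(self, atlas_data):
        _, _, truth = atlas_data
        theta = truth.theta.to_numpy()
        x = theta @ np.full(theta.shape[1], 1.0 / theta.shape[1])
        x = x + 0.001 * np.abs(np.sin(np.arange(len(x))))  # perturb off the manifold
        props, beta, _, it, conv = weighted_nnls_proportions(
            x, theta, np.zeros_like(theta), np.ones(theta.shape[1]), nu=1.0
        )
        beta_plain = nnls(theta, x / x.sum())
        np.testing.assert_allclose(beta, beta_plain, atol=1e-12)
        assert conv and it <= 2

    def test_scale_invariance(self, atlas_data):
        _, _, truth = atlas_data
        x = simdata.mixture_expectation(
            truth, simdata.stage_proportions(truth).loc["PND14"]
        ).to_numpy()
        r1 = deconvolve_sample(x, truth.theta, truth.theta * 0.0, truth.cell_size,
                               truth.cluster_broad)
        r2 = deconvolve_sample(x * 731.0, truth.theta, truth.theta * 0.0, truth.cell_size,
                               truth.cluster_broad)
        np.testing.assert_allclose(r1.proportions, r2.proportions, atol=1e-12)

    def test_permutation_equivariance(self, atlas_data):
        _, _, truth = atlas_data
        x = simdata.mixture_expectation(
            truth, simdata.stage_proportions(truth).loc["PND6"]
        ).to_numpy()
        perm = list(truth.theta.columns)[::-1]
        r1 = deconvolve_sample(x, truth.theta, truth.theta * 0.0, truth.cell_size,
                               truth.cluster_broad)
        r2 = deconvolve_sample(x, truth.theta[perm], (truth.theta * 0.0)[perm],
                               truth.cell_size[perm], truth.cluster_broad)
        np.testing.assert_allclose(
            r1.proportions.loc[perm].to_numpy(), r2.proportions.to_numpy(), atol=1e-9
        )

    def test_cell_size_conversion_on_fixed_beta(self):
        """Doubling S_k halves cluster k's share of p for a fixed beta."""
        beta = np.array([1.0, 1.0])
        s1 = np.array([1.0, 1.0])
        s2 = np.array([1.0, 2.0])
        p1 = (beta / s1) / (beta / s1).sum()
        p2 = (beta / s2) / (beta / s2).sum()
        assert p1[1] == 0.5
        np.testing.assert_allclose(p2, [2 / 3, 1 / 3])

    def test_noisy_cohort_broad_mae(self, qc_atlas, cohort):
        from ovotox.atlas import build_reference

        counts, meta, _, truth = qc_atlas
        bulk, smeta, ctruth = cohort
        ref = build_reference(counts, meta)
        model = CellTypeDeconvolver().fit(ref)
        sub = bulk.to_frame().iloc[:, :36]
        broad = model.predict_broad(sub)
        cb = pd.Series(truth.cluster_broad)
        truth_broad = ctruth.proportions.loc[sub.columns].T.groupby(cb).sum().T
        mae = (broad - truth_broad[broad.columns]).abs().mean().mean()
        assert mae < 0.05


class TestAggregate:
    def test_two_clusters_one_type(self):
        p = pd.Series({"c1": 0.2, "c2": 0.3, "c3": 0.5})
        out = aggregate_broad_types(p, {"c1": "germ", "c2": "germ", "c3": "theca"})
        assert out["germ"] == pytest.approx(0.5)
        assert out.sum() == pytest.approx(p.sum())

    def test_identity_map_is_noop(self):
        p = pd.Series({"c1": 0.4, "c2": 0.6})
        out = aggregate_broad_types(p, {"c1": "a", "c2": "b"})
        np.testing.assert_allclose(out.to_numpy(), [0.4, 0.6])

    def test_unmapped_cluster_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_broad_types(pd.Series({"c1": 1.0}), {})


class TestCompareProportions:
    def test_exact_p_for_separated_groups(self):
        """(1,2,3) vs (10,11,12): two-sided exact p = 2/20 = 0.1."""
        _, p = rank_sum_test([1, 2, 3], [10, 11, 12])
        assert p == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        _, p = rank_sum_test([5.0, 5.0, 6.0], [5.0, 6.0, 5.0])
        assert p == pytest.approx(1.0)

    def test_normal_approximation_close_to_exact(self, rng):
        for _ in range(20):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            _, p_exact = rank_sum_test(x, y, exact_limit=12)
            _, p_norm = rank_sum_test(x, y, exact_limit=0)
            assert abs(p_exact - p_norm) < 0.02

    def test_panel_and_percent_change(self):
        samples = [f"s{i}" for i in range(8)]
        meta = pd.DataFrame(
            {
                "sample_id": samples,
                "stage": ["PND6"] * 4 + ["PND22"] * 4,
                "compound": "control",
                "dose_level": "none",
                "dose_value": "0",
                "plate": "plate1",
            }
        )
        props = pd.DataFrame(
            {"germ": [0.4, 0.42, 0.38, 0.4, 0.1, 0.08, 0.12, 0.1]}, index=samples
        )
        props["granulosa"] = 1 - props["germ"]
        out = compare_proportions(props, meta)
        germ = out[(out["broad_type"] == "germ")
                   & (out["contrast"] == "plate1:control:PND6_vs_PND22")].iloc[0]
        assert germ["pct_change"] == pytest.approx(-75.0)
        assert germ["p"] < 0.05

    def test_small_group_rejected(self):
        meta = pd.DataFrame(
            {
                "sample_id": ["a", "b", "c"],
                "stage": ["PND6", "PND6", "PND22"],
                "compound": "control",
                "dose_level": "none",
                "dose_value": "0",
                "plate": "plate1",
            }
        )
        props = pd.DataFrame({"germ": [0.1, 0.2, 0.3]}, index=["a", "b", "c"])
        with pytest.raises(ValidationError, match="< 2 samples"):
            compare_proportions(props, meta)
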