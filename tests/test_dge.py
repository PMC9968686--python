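"""Differential-expression cascade: filters, moderated statistics, signatures."""

import numpy as np
import pandas as pd
import pytest
from scipy import special as spsp
from scipy import stats as sps

from ovotox.dge import (
    CascadeDE,
    ContrastSpec,
    EBayesParams,
    SignatureSet,
    build_signatures,
    detectable_filter,
    fit_ebayes,
    fold_change,
    max_pairwise_fold_change,
    moderated_stats,
    run_cascade,
    signature_summary,
    squeeze_var,
)
from ovotox.errors import PlateError, ValidationError
from ovotox.preprocess import normalize_log
from ovotox.stats import bh_adjust


class TestDetectableFilter:
    def test_constant_matrix_all_pass(self):
        expr = pd.DataFrame(np.full((3, 4), 2.5), index=["a", "b", "c"],
                            columns=["s1", "s2", "s3", "s4"])
        passing, cutoff = detectable_filter(expr, {"g1": ["s1", "s2"], "g2": ["s3", "s4"]})
        assert cutoff == 2.5
        assert passing == {"a", "b", "c"}  # mean equals cutoff, >= passes

    def test_silent_gene_fails(self):
        expr = pd.DataFrame(
            [[0.0, 0.0, 0.0, 0.0], [1.0, 1.2, 0.9, 1.1], [0.5, 0.6, 0.4, 0.5]],
            index=["silent", "hi", "mid"], columns=["s1", "s2", "s3", "s4"],
        )
        passing, cutoff = detectable_filter(expr, {"a": ["s1", "s2"], "b": ["s3", "s4"]})
        assert "silent" not in passing
        assert cutoff > 0

    def test_hand_built_matrix(self):
        """4x4 matrix evaluated by hand: cutoff 2.5, genes g1/g3/g4 pass."""
        expr = pd.DataFrame(
            [[5, 5, 5, 5], [0, 0, 0, 0], [0, 0, 6, 6], [1, 2, 3, 4]],
            index=["g1", "g2", "g3", "g4"], columns=["s1", "s2", "s3", "s4"], dtype=float,
        )
        groups = {"A": ["s1", "s2"], "B": ["s3", "s4"]}
        passing, cutoff = detectable_filter(expr, groups)
        assert cutoff == 2.5
        assert passing == {"g1", "g3", "g4"}

    def test_empty_group_rejected(self):
        expr = pd.DataFrame([[1.0]], index=["g"], columns=["s"])
        with pytest.raises(ValidationError):
            detectable_filter(expr, {"A": []})


class TestFoldChange:
    def test_identical_means_zero(self):
        expr = pd.DataFrame([[1.0, 1.0, 2.0, 2.0]], index=["g"],
                            columns=["a1", "a2", "b1", "b2"])
        lfc = fold_change(expr, ["a1", "b1"], ["a2", "b2"])
        assert lfc["g"] == 0.0

    def test_boundary_at_log2_1_5(self):
        expr = pd.DataFrame([[1.0, 1.585]], index=["g"], columns=["a", "b"])
        lfc = fold_change(expr, ["a"], ["b"])
        assert abs(lfc["g"]) >= np.log2(1.5)

    def test_antisymmetry(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 6)), index=list("abcde"),
                            columns=[f"s{i}" for i in range(6)])
        ga, gb = ["s0", "s1", "s2"], ["s3", "s4", "s5"]
        np.testing.assert_allclose(
            fold_change(expr, ga, gb), -fold_change(expr, gb, ga), atol=1e-12
        )

    def test_overlapping_groups_rejected(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["a", "b"])
        with pytest.raises(ValidationError):
            fold_change(expr, ["a"], ["a", "b"])

    def test_max_pairwise_spans_extremes(self):
        expr = pd.DataFrame([[0.0, 0.0, 1.0, 1.0, 3.0, 3.0]], index=["g"],
                            columns=[f"s{i}" for i in range(6)])
        groups = {"p6": ["s0", "s1"], "p14": ["s2", "s3"], "p22": ["s4", "s5"]}
        assert max_pairwise_fold_change(expr, groups)["g"] == pytest.approx(3.0)


class TestFitEbayes:
    def test_parameter_recovery_from_prior(self):
        """(d0=4, s0^2=2), 5000 genes, d_g=4: estimates within 15%."""
        rng = np.random.default_rng(42)
        d0, s02, dg, n = 4.0, 2.0, 4, 5000
        sigma2 = s02 * d0 / rng.chisquare(d0, n)
        s2 = sigma2 * rng.chisquare(dg, n) / dg
        est = fit_ebayes(s2, dg)
        assert abs(est.d0 - d0) / d0 < 0.15
        assert abs(est.s0_sq - s02) / s02 < 0.15

    def test_identical_variances_give_infinite_prior_df(self):
        est = fit_ebayes(np.full(100, 3.3), 4)
        assert np.isinf(est.d0)
        assert est.s0_sq == pytest.approx(3.3)

    def test_d0_decreases_with_spread(self):
        rng = np.random.default_rng(1)
        base = rng.chisquare(4, 3000) / 4
        d0s = []
        for spread in (0.2, 0.5, 1.0, 2.0):
            s2 = base * np.exp(rng.normal(0, spread, size=base.size))
            d0s.append(fit_ebayes(s2, 4).d0)
        assert all(a > b for a, b in zip(d0s, d0s[1:]))

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            fit_ebayes(np.zeros(100), 4)


class TestModeratedStats:
    def _toy(self):
        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0, 2.0, 3.0, 4.0]], index=["g"],
            columns=["a1", "a2", "a3", "b1", "b2", "b3"],
        )
        groups = {"A": ["a1", "a2", "a3"], "B": ["b1", "b2", "b3"]}
        return expr, groups

    def test_hand_computed_moderated_t(self):
        """means 2 vs 3, s2=1, d0=4, s0^2=2 -> s~2=1.5, t = 1 exactly."""
        expr, groups = self._toy()
        out = moderated_stats(expr, groups, EBayesParams(4.0, 2.0))
        assert out.loc["g", "s2"] == pytest.approx(1.0, abs=1e-12)
        assert out.loc["g", "s2_moderated"] == pytest.approx(1.5, abs=1e-12)
        assert out.loc["g", "stat"] == pytest.approx(1.0, abs=1e-10)
        # total df = d0 + d_g = 4 + (6 - 2) = 8
        assert out.loc["g", "p"] == pytest.approx(2 * sps.t.sf(1.0, 8), abs=1e-12)

    def test_d0_zero_equals_ordinary_t(self, rng):
        expr = pd.DataFrame(rng.normal(size=(40, 8)), index=[f"g{i}" for i in range(40)],
                            columns=[f"s{i}" for i in range(8)])
        groups = {"A": [f"s{i}" for i in range(4)], "B": [f"s{i}" for i in range(4, 8)]}
        out = moderated_stats(expr, groups, EBayesParams(0.0, 1.0))
        t_ref, p_ref = sps.ttest_ind(
            expr[groups["B"]], expr[groups["A"]], axis=1, equal_var=True
        )
        np.testing.assert_allclose(out["stat"], t_ref, atol=1e-12)
        np.testing.assert_allclose(out["p"], p_ref, atol=1e-12)

    def test_d0_infinite_uses_prior_variance(self):
        expr, groups = self._toy()
        out = moderated_stats(expr, groups, EBayesParams(float("inf"), 2.0))
        assert out.loc["g", "s2_moderated"] == pytest.approx(2.0)
        c = np.sqrt(2.0 / 3.0)
        assert out.loc["g", "stat"] == pytest.approx(1.0 / (np.sqrt(2.0) * c), abs=1e-12)

    def test_continuity_as_d0_vanishes(self, rng):
        expr = pd.DataFrame(rng.normal(size=(20, 6)), index=[f"g{i}" for i in range(20)],
                            columns=[f"s{i}" for i in range(6)])
        groups = {"A": ["s0", "s1", "s2"], "B": ["s3", "s4", "s5"]}
        t0 = moderated_stats(expr, groups, EBayesParams(0.0, 1.0))["stat"]
        prev = None
        for d0 in (1.0, 1e-2, 1e-4, 1e-6):
            t = moderated_stats(expr, groups, EBayesParams(d0, 1.0))["stat"]
            gap = np.max(np.abs(t - t0))
            if prev is not None:
                assert gap < prev + 1e-12
            prev = gap
        assert prev < 1e-4

    def test_multigroup_f_matches_anova_at_d0_zero(self, rng):
        expr = pd.DataFrame(rng.normal(size=(15, 9)), index=[f"g{i}" for i in range(15)],
                            columns=[f"s{i}" for i in range(9)])
        groups = {"A": ["s0", "s1", "s2"], "B": ["s3", "s4", "s5"], "C": ["s6", "s7", "s8"]}
        out = moderated_stats(expr, groups, EBayesParams(0.0, 1.0))
        f_ref, p_ref = sps.f_oneway(
            expr[groups["A"]], expr[groups["B"]], expr[groups["C"]], axis=1
        )
        np.testing.assert_allclose(out["stat"], f_ref, atol=1e-10)
        np.testing.assert_allclose(out["p"], p_ref, atol=1e-10)


class TestBhAdjust:
    def test_single_value_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.05]), [0.05])

    def test_hand_stepup(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_adjusted_at_least_raw_and_monotone(self, rng):
        p = rng.uniform(size=200)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])


class TestCascade:
    def test_conjunction_of_filters(self, cohort):
        bulk, meta, _ = cohort
        expr = normalize_log(bulk)
        res = run_cascade(expr, meta, ContrastSpec("development", plate="plate1"))
        deg = set(res.index[res["deg"]])
        manual = set(res.index[res["pass_detectable"] & res["pass_fc"] & res["pass_stat"]])
        assert deg == manual
        assert not (res["deg"] & ~res["pass_fc"]).any()

    def test_bh_universe_is_detectable_set(self, cohort):
        bulk, meta, _ = cohort
        expr = normalize_log(bulk)
        res = run_cascade(
            expr, meta,
            ContrastSpec("exposure", compound="DES", stage="PND6", dose_level="high"),
        )
        det = res[res["pass_detectable"]]
        assert det["p"].notna().all()
        assert res.loc[~res["pass_detectable"], "p"].isna().all()
        np.testing.assert_allclose(
            det["adj_p"].to_numpy(), bh_adjust(det["p"].to_numpy()), atol=1e-12
        )

    def test_cross_plate_contrast_rejected(self, cohort):
        bulk, meta, _ = cohort
        expr = normalize_log(bulk)
        bad = meta.copy()
        # scatter the DES samples across both plates
        des = bad["compound"] == "DES"
        bad.loc[des, "plate"] = np.where(
            np.arange(des.sum()) % 2 == 0, "plate1", "plate2"
        )
        with pytest.raises(PlateError):
            run_cascade(expr, bad,
                        ContrastSpec("exposure", compound="DES", stage="PND6",
                                     dose_level="high"))

    def test_direction_follows_fold_change_sign(self, cohort):
        bulk, meta, _ = cohort
        expr = normalize_log(bulk)
        res = run_cascade(
            expr, meta,
            ContrastSpec("exposure", compound="KTZ", stage="PND6", dose_level="high"),
        )
        degs = res[res["deg"]]
        assert ((degs["log2fc"] > 0) == (degs["direction"] == "up")).all()


class TestSignatures:
    def _sig(self):
        sig = SignatureSet()
        sig.add("DES", "PND6", "low", {"g1": "up", "g2": "down"})
        sig.add("DES", "PND6", "high", {"g1": "up", "g3": "down"})
        sig.add("KTZ", "PND6", "high", {"g1": "down", "g4": "up"})
        sig.development = {"g2", "g9"}
        return sig

    def test_empty_results_empty_signatures(self):
        sig = build_signatures({})
        assert sig.calls == {} and sig.development == set()

    def test_union_has_set_semantics(self):
        sig = self._sig()
        assert sig.union("DES") == {"g1", "g2", "g3"}

    def test_counts_conservation(self):
        counts = self._sig().counts()
        assert (counts["n_up"] + counts["n_down"]).equals(counts["n_total"])

    def test_direction_classes(self):
        sig = self._sig()
        assert sig.direction_class("DES", "g1") == "over"
        assert sig.direction_class("DES", "g2") == "under"

    def test_summary_arithmetic(self):
        s = signature_summary(self._sig())
        assert s["total"] == len({"g1", "g2", "g3", "g4", "g9"})
        assert s["development"] == 2
        assert s["DES"] == 3 and s["KTZ"] == 2
        assert s["shared"] == 1  # g1
        assert s["DES_low"] == 2 and s["DES_high"] == 2 and s["DES_PND6"] == 3

    def test_json_roundtrip(self, tmp_path):
        sig = self._sig()
        sig.to_json(tmp_path / "s.json")
        back = SignatureSet.from_json(tmp_path / "s.json")
        assert back.calls == sig.calls and back.development == sig.development

    def test_table_parser(self, tmp_path):
        rows = [
            "gene\tcompound\tstage\tdose_level\tdirection",
            "g1\tDES\tPND6\tlow\tup",
            "g2\tDES\tPND6\tlow\tdown",
            "g1\tKTZ\tPND14\thigh\tdown",
            "g7\tdevelopment\tall\tnone\t",
        ]
        (tmp_path / "sig.tsv").write_text("\n".join(rows) + "\n")
        sig = SignatureSet.from_table(tmp_path / "sig.tsv")
        s = signature_summary(sig)
        assert s["DES"] == 2 and s["KTZ"] == 1 and s["shared"] == 1
        assert s["development"] == 1 and s["total"] == 3  # g1, g2, g7
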