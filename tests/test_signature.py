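"""Dormancy signature derivation: BH adjustment, DEG selection, z-scoring,
the recurrence/quantile rules, ordering, and sample scoring."""

import numpy as np
import pandas as pd
import pytest

from dormtrace import signature as sig
from dormtrace import synthetic as syn


class TestAdjustPvalues:
    def test_all_ones_stay_one(self):
        np.testing.assert_array_equal(sig.adjust_pvalues([1.0, 1.0, 1.0]), [1, 1, 1])

    def test_single_pvalue_unchanged(self):
        assert sig.adjust_pvalues([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_bh_example(self):
        padj = sig.adjust_pvalues([0.01, 0.02, 0.03, 0.5])
        np.testing.assert_allclose(padj, [0.04, 0.04, 0.04, 0.5])

    def test_monotone_in_rank(self, rng):
        p = rng.random(200)
        padj = sig.adjust_pvalues(p)
        order = np.argsort(p)
        assert (np.diff(padj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sig.adjust_pvalues([0.5, 1.5])


class TestSelectDegs:
    def mk(self, log2fc, padj):
        return pd.DataFrame(
            {"gene": [f"G{i}" for i in range(len(log2fc))],
             "log2fc": log2fc, "padj": padj}
        )

    def test_signature_preset_thresholds(self):
        de = self.mk([1.2, 0.9, 1.2], [0.005, 0.001, 0.02])
        selected = sig.select_degs(de)
        assert list(selected) == ["G0"]  # strict >1 and <0.01

    def test_general_preset_uses_1p5_fold(self):
        de = self.mk([0.7, 0.5], [0.001, 0.001])
        selected = sig.select_degs(de, *sig.GENERAL_PRESET)
        assert list(selected) == ["G0"]  # log2(1.5) ~ 0.585

    def test_downregulated_genes_selected_by_magnitude(self):
        de = self.mk([-2.0], [0.001])
        assert list(sig.select_degs(de)) == ["G0"]


class TestZscoreMatrix:
    def test_constant_gene_flagged_and_zeroed(self):
        expr = pd.DataFrame({"a": [1.0, 1.0], "b": [1.0, 2.0]}, index=["g1", "g2"])
        z, flagged = sig.zscore_matrix(expr, ["a", "b"])
        assert list(flagged) == ["g1"]
        assert (z.loc["g1"] == 0).all()

    def test_normalization_identity(self, rng):
        expr = pd.DataFrame(
            rng.normal(5, 2, (50, 8)), columns=[f"s{i}" for i in range(8)]
        )
        z, _ = sig.zscore_matrix(expr, list(expr.columns))
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1, atol=1e-9)

    def test_two_sample_hand_example(self):
        expr = pd.DataFrame({"a": [0.0], "b": [2.0]}, index=["g"])
        z, _ = sig.zscore_matrix(expr, ["a", "b"])
        np.testing.assert_allclose(
            z.loc["g"], [-1 / np.sqrt(2), 1 / np.sqrt(2)]
        )

    def test_extension_applies_subset_moments(self):
        expr = pd.DataFrame(
            {"a": [0.0], "b": [2.0], "held_out": [4.0]}, index=["g"]
        )
        z, _ = sig.zscore_matrix(expr, ["a", "b"], extend_to_all=True)
        # held-out z uses mean=1, sd=sqrt(2) from the subset
        assert z.loc["g", "held_out"] == pytest.approx(3 / np.sqrt(2))

    def test_single_sample_subset_rejected(self):
        expr = pd.DataFrame({"a": [1.0]})
        with pytest.raises(ValueError):
            sig.zscore_matrix(expr, ["a"])


class TestDeriveSignature:
    def zmat(self, rows, samples):
        return pd.DataFrame(rows, columns=samples)

    def test_recurrently_high_gene_enters_up_list(self):
        samples = [f"P{i}" for i in range(3)] + [f"D{i}" for i in range(6)]
        z = pd.DataFrame(
            [[0.05, -0.1, 0.02] + [2.0] * 6], index=["hit"], columns=samples
        )
        res = sig.derive_dormancy_signature(z, samples[3:])
        assert res.up_genes == ["hit"]

    def test_five_of_six_recurrence_is_excluded(self):
        samples = [f"P{i}" for i in range(3)] + [f"D{i}" for i in range(6)]
        z = pd.DataFrame(
            [[0.0, 0.0, 0.0, 2.0, 2.0, 2.0, 2.0, 2.0, -0.5]],
            index=["g"], columns=samples,
        )
        res = sig.derive_dormancy_signature(z, samples[3:])
        assert res.up_genes == []

    def test_down_rule_is_symmetric(self):
        samples = [f"P{i}" for i in range(3)] + [f"D{i}" for i in range(6)]
        z = pd.DataFrame(
            [[0.5, 0.2, 0.1] + [-2.0] * 6], index=["low"], columns=samples
        )
        res = sig.derive_dormancy_signature(z, samples[3:])
        assert res.down_genes == ["low"]
        assert res.up_genes == []

    def test_order_invariance_to_row_and_column_shuffles(self, rng):
        samples = [f"P{i}" for i in range(4)] + [f"D{i}" for i in range(6)]
        z = pd.DataFrame(
            rng.normal(size=(30, 10)),
            index=[f"g{i}" for i in range(30)],
            columns=samples,
        )
        z.iloc[:5, 4:] += 3.0
        res1 = sig.derive_dormancy_signature(z, samples[4:])
        shuffled = z.sample(frac=1, axis=0, random_state=1).sample(
            frac=1, axis=1, random_state=2
        )
        res2 = sig.derive_dormancy_signature(shuffled, samples[4:])
        assert res1.up_genes == res2.up_genes
        assert res1.down_genes == res2.down_genes

    def test_planted_signature_round_trip(self):
        n_up = n_down = 50
        genes = [f"G{i:04d}" for i in range(500)]
        up, down = genes[:n_up], genes[n_up : n_up + n_down]
        data = syn.generate_expression_dataset(
            500, 6, 6, 4, up, down, effect_size=4.0, sigma=0.5, seed=17
        )
        degs = sig.select_degs(data["de"])
        ann = data["annotations"]
        subset = list(ann.loc[ann["group"].isin(["POT", "dormancy"]), "sample"])
        dorm = list(ann.loc[ann["group"] == "dormancy", "sample"])
        z, _ = sig.zscore_matrix(data["expr"].loc[data["expr"].index.isin(degs)], subset)
        res = sig.derive_dormancy_signature(z, dorm)
        for found, planted in ((set(res.up_genes), set(up)), (set(res.down_genes), set(down))):
            precision = len(found & planted) / max(len(found), 1)
            recall = len(found & planted) / len(planted)
            assert precision >= 0.9
            assert recall >= 0.9

    def test_ordering_keys_reported_and_sorted(self):
        samples = [f"P{i}" for i in range(3)] + [f"D{i}" for i in range(6)]
        z = pd.DataFrame(
            [
                [0.0, 0.0, 0.0, 2.0, 2.1, 1.9, 2.0, 2.0, 2.0],
                [0.0, 0.0, 0.0, 3.0, 0.5, 4.0, 1.0, 2.0, 0.4],
            ],
            index=["tight", "noisy"], columns=samples,
        )
        res = sig.derive_dormancy_signature(z, samples[3:])
        assert res.up_genes[0] == "tight"
        assert {"cv", "cumulative_z", "recurrence"} <= set(res.stats.columns)


class TestScoreSamples:
    def test_one_gene_signature_equals_its_z(self):
        z = pd.DataFrame({"a": [1.5], "b": [-0.5]}, index=["g"])
        scores = sig.score_samples(z, ["g"])
        assert scores["a"] == 1.5

    def test_zero_matrix_scores_zero(self):
        z = pd.DataFrame(np.zeros((5, 3)), index=[f"g{i}" for i in range(5)])
        assert (sig.score_samples(z, ["g0", "g1"]) == 0).all()

    def test_planted_up_score_separates_groups(self):
        genes = [f"G{i:04d}" for i in range(500)]
        data = syn.generate_expression_dataset(
            500, 4, 6, 10, genes[:20], [], effect_size=4.0, sigma=0.5, seed=19
        )
        ann = data["annotations"]
        subset = list(ann["sample"])
        z, _ = sig.zscore_matrix(data["expr"], subset)
        scores = sig.score_samples(z, genes[:20])
        dorm = ann.loc[ann["group"] == "dormancy", "sample"]
        pot = ann.loc[ann["group"] == "POT", "sample"]
        assert scores[dorm].mean() - scores[pot].mean() >= 2.0

    def test_missing_all_genes_rejected(self):
        z = pd.DataFrame({"a": [1.0]}, index=["g"])
        with pytest.raises(ValueError):
            sig.score_samples(z, ["absent"])
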