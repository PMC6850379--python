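"""RPKM computation, bias classification rules, enrichment contingency."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fastz import (
    SimTruth,
    annotate_genes,
    classify_sex_bias,
    classify_tissue_bias,
    enrichment_test,
    rpkm,
    simulate_counts,
    simulate_expression,
)
from fastz.expression import mean_rpkm_by_sex


class TestRPKM:
    def test_round_number_example(self):
        # 10 reads, 1 Mb library, 1 kb gene -> RPKM 10
        counts = np.array([10.0, 999990.0])
        lengths = np.array([1000.0, 10000.0])
        assert rpkm(counts, lengths)[0] == pytest.approx(10.0, rel=1e-6)

    def test_zero_count_gene_is_zero(self):
        out = rpkm(np.array([0.0, 100.0]), np.array([500.0, 500.0]))
        assert out[0] == 0.0

    def test_equal_counts_equal_lengths_equal_rpkm(self):
        out = rpkm(np.full(5, 7.0), np.full(5, 300.0))
        assert np.allclose(out, out[0])

    def test_zero_library_and_zero_length_rejected(self):
        with pytest.raises(ValueError, match="library"):
            rpkm(np.zeros(3), np.ones(3))
        with pytest.raises(ValueError, match="length"):
            rpkm(np.ones(3), np.zeros(3))


class TestSexBias:
    @pytest.mark.parametrize(
        "f,m,expected",
        [
            (3.0, 1.5, "female"),   # ratio 2.0
            (1.0, 2.0, "male"),     # ratio 0.5
            (1.5, 1.0, "unbiased"), # ratio exactly 1.5: strict inequality
            (0.66, 1.0, "unbiased"),
            (1.0, 1.0, "unbiased"),
            (2.0, 0.0, "female"),   # infinite ratio
        ],
    )
    def test_threshold_rule(self, f, m, expected):
        assert classify_sex_bias(f, m)[0] == expected

    def test_doubly_unexpressed_flagged(self):
        bias, unexpressed = classify_sex_bias(0.0, 0.0)
        assert bias == "unbiased" and unexpressed

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            classify_sex_bias(-1.0, 2.0)

    def test_classification_invariant_to_library_scaling(self):
        truth = SimTruth(n_genes=150, seed=71)
        genes = simulate_counts(truth)
        counts, samples = simulate_expression(genes, truth, seed=72)
        lengths = pd.Series({g.gene_id: g.L_s + g.L_n for g in genes})
        a = mean_rpkm_by_sex(counts, lengths, samples)
        scaled = counts.copy()
        scaled.iloc[:, 0] *= 17  # depth change in one library
        b = mean_rpkm_by_sex(scaled, lengths, samples)
        labels_a = [classify_sex_bias(f, m)[0] for f, m in zip(a.rpkm_f, a.rpkm_m)]
        labels_b = [classify_sex_bias(f, m)[0] for f, m in zip(b.rpkm_f, b.rpkm_m)]
        assert labels_a == labels_b

    def test_recovery_at_strong_fold_change(self):
        truth = SimTruth(n_genes=1500, seed=73)
        genes = simulate_counts(truth)
        counts, samples = simulate_expression(
            genes, truth, bias_fold=4.0, dispersion=0.05, seed=74
        )
        lengths = pd.Series({g.gene_id: g.L_s + g.L_n for g in genes})
        levels = mean_rpkm_by_sex(counts, lengths, samples)
        hits = 0
        for g in genes:
            row = levels.loc[g.gene_id]
            if classify_sex_bias(row.rpkm_f, row.rpkm_m)[0] == g.true_bias:
                hits += 1
        assert hits / len(genes) > 0.9

    def test_no_signal_control_is_small_and_symmetric(self):
        truth = SimTruth(n_genes=1500, seed=75)
        genes = simulate_counts(truth)
        counts, samples = simulate_expression(genes, truth, bias_fold=1.0, seed=76)
        lengths = pd.Series({g.gene_id: g.L_s + g.L_n for g in genes})
        levels = mean_rpkm_by_sex(counts, lengths, samples)
        labels = [
            classify_sex_bias(f, m)[0]
            for f, m in zip(levels.rpkm_f, levels.rpkm_m)
        ]
        n_f, n_m = labels.count("female"), labels.count("male")
        assert (n_f + n_m) / len(labels) < 0.25  # mostly unbiased
        if n_f + n_m:
            p = stats.binomtest(n_f, n_f + n_m, 0.5).pvalue
            assert p > 1e-3  # no systematic skew toward either sex


class TestTissueBias:
    def test_threshold_combinations(self):
        table = pd.DataFrame(
            {
                "log2FC": [2.0, 3.0, -2.0, 1.0, -4.0],
                "padj": [0.01, 0.2, 0.01, 0.01, 0.04],
            },
            index=[f"g{i}" for i in range(5)],
        )
        labels = classify_tissue_bias(table)
        assert list(labels) == ["ovary", "none", "gut", "none", "gut"]

    def test_missing_padj_skipped_with_warning(self):
        table = pd.DataFrame(
            {"log2FC": [2.0, 2.0], "padj": [0.01, np.nan]}, index=["a", "b"]
        )
        with pytest.warns(UserWarning, match="lack adjusted p"):
            labels = classify_tissue_bias(table)
        assert "b" not in labels.index


class TestEnrichment:
    def test_study_counts_are_significant(self):
        # Z chromosome: 6 gut, 6 ovary; autosomes: 153 gut, 40 ovary
        chi2, p = enrichment_test(np.array([[6, 6], [153, 40]]))
        expected, pe, _, _ = (
            stats.chi2_contingency(np.array([[6, 6], [153, 40]]), correction=False)
        )[0:4]
        assert chi2 == pytest.approx(expected)
        assert p < 0.05

    def test_proportional_table_gives_zero_statistic(self):
        chi2, p = enrichment_test(np.array([[10, 10], [10, 10]]))
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_small_expected_counts_warn(self):
        with pytest.warns(UserWarning, match="below 5"):
            enrichment_test(np.array([[2, 3], [3, 2]]))

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            enrichment_test(np.array([[0, 0], [5, 5]]))


class TestAnnotateGenes:
    def test_partition_of_expressed_genes(self):
        truth = SimTruth(n_genes=200, seed=77)
        genes = simulate_counts(truth)
        counts, samples = simulate_expression(genes, truth, seed=78)
        lengths = pd.Series({g.gene_id: g.L_s + g.L_n for g in genes})
        chrom = pd.Series({g.gene_id: g.chrom_class for g in genes})
        annot = annotate_genes(counts, lengths, samples, chrom)
        assert set(annot["bias"]) <= {"female", "male", "unbiased"}
        assert len(annot) == len(genes)
        assert annot["mean_rpkm"].min() >= 0
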