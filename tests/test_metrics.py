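"""Evaluation metrics against hand values and brute-force oracles."""

from itertools import combinations
from math import comb

import numpy as np
import pytest
import scipy.stats

from scsdae.metrics import (
    ari,
    cmd,
    correlation_matrix,
    fdr_tpr,
    gene_gene_significance,
    group_mae,
    kw_de_eval,
    pairwise_pearson_truth,
    spearman_pvalues,
    top_variable_genes,
)


class TestCorrelationMatrix:
    def test_identical_rows_all_ones(self):
        X = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        np.testing.assert_allclose(correlation_matrix(X), np.ones((2, 2)))

    def test_anticorrelated_rows(self):
        X = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        R = correlation_matrix(X)
        assert R[0, 1] == pytest.approx(-1.0)

    def test_matches_scalar_oracle(self, rng):
        X = rng.normal(size=(5, 10))
        R = correlation_matrix(X)
        for i, j in combinations(range(5), 2):
            r, _ = scipy.stats.pearsonr(X[i], X[j])
            assert R[i, j] == pytest.approx(r, abs=1e-12)

    def test_spearman_method(self, rng):
        X = rng.normal(size=(4, 20))
        R = correlation_matrix(X, method="spearman")
        for i, j in combinations(range(4), 2):
            r, _ = scipy.stats.spearmanr(X[i], X[j])
            assert R[i, j] == pytest.approx(r, abs=1e-12)

    def test_genes_axis(self, rng):
        X = rng.normal(size=(6, 4))
        np.testing.assert_allclose(correlation_matrix(X, axis="genes"),
                                   correlation_matrix(X.T), atol=1e-12)

    def test_zero_variance_vector_warns_and_zeroes(self):
        X = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.warns(UserWarning):
            R = correlation_matrix(X)
        assert R[0, 1] == 0.0 and R[0, 0] == 1.0

    def test_too_few_vectors(self):
        with pytest.raises(ValueError):
            correlation_matrix(np.ones((1, 5)))


class TestCMD:
    def test_identical_matrices_zero(self, rng):
        X = rng.normal(size=(8, 30))
        R = correlation_matrix(X)
        assert cmd(R, R) == pytest.approx(0.0, abs=1e-12)

    def test_hand_case(self):
        R1 = np.eye(2)
        R2 = np.ones((2, 2))
        assert cmd(R1, R2) == pytest.approx(1 - 1 / np.sqrt(2), abs=1e-12)
        assert cmd(R1, R2) == pytest.approx(0.2929, abs=1e-4)

    def test_symmetry_and_range(self, rng):
        for _ in range(10):
            R1 = correlation_matrix(rng.normal(size=(6, 25)))
            R2 = correlation_matrix(rng.normal(size=(6, 25)))
            d = cmd(R1, R2)
            assert d == pytest.approx(cmd(R2, R1), abs=1e-12)
            assert -1e-12 <= d <= 1.0 + 1e-12

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            cmd(np.zeros((2, 2)), np.eye(2))


class TestGeneGeneSignificance:
    def test_perfectly_correlated_pair_flagged(self, rng):
        g1 = rng.normal(size=1000)
        X = np.column_stack([g1, g1 + 1.0, rng.normal(size=1000)])
        det = gene_gene_significance(X)
        assert det[0, 1] and det[1, 0]
        assert not det.diagonal().any()

    def test_alpha_zero_flags_nothing(self, rng):
        X = rng.normal(size=(100, 5))
        assert not gene_gene_significance(X, alpha_fw=0.0).any()

    def test_familywise_error_controlled_under_null(self):
        # independent genes: probability of any flag should be <= q
        n_reps, hits = 20, 0
        for seed in range(n_reps):
            X = np.random.default_rng(seed).normal(size=(1000, 50))
            hits += gene_gene_significance(X, alpha_fw=0.05).any()
        se = np.sqrt(0.05 * 0.95 / n_reps)
        assert hits / n_reps <= 0.05 + 3 * se

    def test_exact_small_sample_branch(self, rng):
        X = rng.normal(size=(6, 3))
        rho, p = spearman_pvalues(X)
        assert np.all((p >= 0) & (p <= 1))
        # a monotone pair at n=6: exact two-sided permutation p = 2/6!
        Y = np.column_stack([np.arange(6.0), np.arange(6.0) ** 2])
        _, p2 = spearman_pvalues(Y)
        assert p2[0, 1] == pytest.approx(2 / 720)

    def test_constant_gene_not_significant(self, rng):
        X = np.column_stack([np.ones(50), rng.normal(size=50)])
        with pytest.warns(UserWarning):
            det = gene_gene_significance(X)
        assert not det.any()


class TestFdrTpr:
    def test_perfect_detection(self):
        truth = np.array([True, True, False, False])
        det = np.zeros((4, 4), dtype=bool)
        det[0, 1] = det[1, 0] = True
        fdr, tpr = fdr_tpr(det, truth)
        assert fdr == 0.0 and tpr == 1.0

    def test_empty_detection(self):
        fdr, tpr = fdr_tpr(np.zeros((4, 4), dtype=bool),
                           np.array([True, True, False, False]))
        assert fdr == 0.0 and tpr == 0.0

    def test_matches_enumerated_confusion_counts(self, rng):
        g = 10
        truth = rng.random(g) < 0.4
        det = np.zeros((g, g), dtype=bool)
        iu = np.triu_indices(g, 1)
        flags = rng.random(len(iu[0])) < 0.3
        det[iu] = flags
        det |= det.T
        tp = fp = 0
        for (i, j), f in zip(zip(*iu), flags):
            if f and truth[i] and truth[j]:
                tp += 1
            elif f:
                fp += 1
        n_true = sum(1 for i, j in combinations(range(g), 2) if truth[i] and truth[j])
        fdr, tpr = fdr_tpr(det, truth)
        assert fdr == pytest.approx(fp / max(1, fp + tp))
        if n_true:
            assert tpr == pytest.approx(tp / n_true)


class TestKwDeEval:
    def test_power_under_strong_shift(self):
        sens = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(0, 1, (400, 50))
            truth = np.zeros(50, dtype=bool)
            truth[:10] = True
            groups = np.repeat([0, 1], 200)
            X[np.ix_(groups == 1, np.arange(10))] += 5.0  # 5 sigma shift
            s, _ = kw_de_eval(X, groups, truth, 0.05)
            sens.append(s)
        assert np.mean(sens) >= 0.95

    def test_specificity_under_null(self):
        specs = []
        for seed in range(10):
            X = np.random.default_rng(seed).normal(size=(200, 100))
            truth = np.zeros(100, dtype=bool)
            _, sp = kw_de_eval(X, np.repeat([0, 1], 100), truth, 0.05)
            specs.append(sp)
        se = np.sqrt(0.05 * 0.95 / (100 * 10))
        assert np.mean(specs) >= 0.95 - 3 * se

    def test_identical_groups_flag_nothing(self, rng):
        half = rng.normal(size=(5, 4))
        X = np.vstack([half, half])  # group 2 is an exact copy of group 1
        groups = np.repeat([0, 1], 5)
        sens, spec = kw_de_eval(X, groups, np.zeros(4, dtype=bool))
        assert spec == 1.0

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            kw_de_eval(np.ones((3, 2)), [0, 0, 1], np.zeros(2, dtype=bool))


class TestGroupMae:
    def test_perfect_imputation(self):
        X = np.random.default_rng(0).normal(size=(10, 6))
        total, a, b = group_mae(X, X, [4, 5], np.repeat([0, 1], 5))
        assert total == a == b == 0.0

    def test_hand_case_one_group_off(self):
        truth = np.zeros((4, 2))
        imputed = np.zeros((4, 2))
        groups = np.array([0, 0, 1, 1])
        imputed[groups == 0] = 0.5
        total, a, b = group_mae(imputed, truth, [0, 1], groups)
        assert a == pytest.approx(0.5) and b == 0.0
        assert total == pytest.approx(0.25)

    def test_total_is_weighted_mean(self, rng):
        truth = rng.normal(size=(9, 5))
        imputed = truth + rng.normal(size=(9, 5))
        groups = np.array([0] * 3 + [1] * 6)
        total, a, b = group_mae(imputed, truth, np.arange(5), groups)
        assert total == pytest.approx((3 * a + 6 * b) / 9)


class TestAri:
    def test_identical_partitions(self):
        assert ari([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0

    def test_label_permutation_invariance(self):
        assert ari([0, 0, 1, 1, 2], [5, 5, 3, 3, 9]) == 1.0

    def test_matches_pair_counting_oracle(self, rng):
        # brute-force ARI from the pair-level contingency counts
        a = rng.integers(0, 3, 30)
        b = rng.integers(0, 3, 30)
        n = len(a)
        sums = {"11": 0, "00": 0, "10": 0, "01": 0}
        for i, j in combinations(range(n), 2):
            same_a, same_b = a[i] == a[j], b[i] == b[j]
            sums["11" if same_a and same_b else
                 "00" if not same_a and not same_b else
                 "10" if same_a else "01"] += 1
        total = comb(n, 2)
        index = sums["11"]
        exp = (sums["11"] + sums["10"]) * (sums["11"] + sums["01"]) / total
        mx = 0.5 * ((sums["11"] + sums["10"]) + (sums["11"] + sums["01"]))
        expected = (index - exp) / (mx - exp)
        assert ari(a, b) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ari([0, 1], [0, 1, 2])


class TestPairwisePearsonTruth:
    def test_identity_gives_ones(self, rng):
        X = rng.normal(size=(6, 20))
        np.testing.assert_allclose(pairwise_pearson_truth(X, X), 1.0, atol=1e-12)

    def test_negated_gives_minus_ones(self, rng):
        X = rng.normal(size=(6, 20))
        np.testing.assert_allclose(pairwise_pearson_truth(-X + 3.0, X), -1.0, atol=1e-12)

    def test_matches_scalar_oracle(self, rng):
        A = rng.normal(size=(5, 15))
        B = rng.normal(size=(5, 15))
        r = pairwise_pearson_truth(A, B)
        for i in range(5):
            expected, _ = scipy.stats.pearsonr(A[i], B[i])
            assert r[i] == pytest.approx(expected, abs=1e-12)


def test_top_variable_genes(rng):
    X = rng.normal(size=(30, 10))
    X[:, 3] *= 10
    X[:, 7] *= 5
    idx = top_variable_genes(X, 2)
    assert set(idx) == {3, 7}
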