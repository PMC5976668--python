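"""Normalization, batch centering, and two-group ANOVA + BH differential expression."""
import numpy as np
import pandas as pd
import pytest
import scipy.stats

from fatiguesig import (
    SimConfig,
    differential_expression,
    generate_dataset,
    log2_transform,
    quantile_normalize,
    remove_batch_effects,
    score_genes,
)
from fatiguesig.errors import DataError

from conftest import make_labels, make_matrix


class TestLog2:
    def test_exact_powers(self):
        matrix = make_matrix([[2, 4], [8, 16]])
        out = log2_transform(matrix)
        assert out.to_numpy().tolist() == [[1, 2], [3, 4]]
        assert log2_transform(make_matrix([[8.0]])).iloc[0, 0] == 3.0
        assert log2_transform(make_matrix([[1.0]])).iloc[0, 0] == 0.0

    def test_nonpositive_value_names_gene_and_sample(self):
        matrix = make_matrix([[2, 4], [0, 16]])
        with pytest.raises(DataError, match=r"g2.*s1"):
            log2_transform(matrix)


class TestQuantileNormalize:
    def test_hand_computed_rank_mean(self):
        matrix = make_matrix(np.array([[2, 1], [4, 3], [6, 5], [8, 7]]))
        out = quantile_normalize(matrix)
        expected = np.array([[1.5, 1.5], [3.5, 3.5], [5.5, 5.5], [7.5, 7.5]])
        np.testing.assert_allclose(out.to_numpy(), expected)

    def test_identical_columns_are_a_fixed_point(self):
        col = np.array([3.0, 1.0, 2.0, 5.0])
        matrix = make_matrix(np.column_stack([col, col, col]))
        pd.testing.assert_frame_equal(quantile_normalize(matrix), matrix)

    def test_column_multisets_identical_and_means_equal(self):
        rng = np.random.default_rng(4)
        matrix = make_matrix(rng.normal(size=(100, 10)))
        out = quantile_normalize(matrix)
        sorted_cols = np.sort(out.to_numpy(), axis=0)
        np.testing.assert_allclose(sorted_cols, sorted_cols[:, [0] * 10])
        np.testing.assert_allclose(out.mean(axis=0), out.mean(axis=0).iloc[0])

    def test_idempotent(self):
        rng = np.random.default_rng(8)
        matrix = make_matrix(rng.normal(size=(60, 6)))
        once = quantile_normalize(matrix)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(twice.to_numpy(), once.to_numpy(), atol=1e-12)

    def test_single_sample_is_noop(self, caplog):
        matrix = make_matrix([[1.0], [2.0]])
        out = quantile_normalize(matrix)
        pd.testing.assert_frame_equal(out, matrix)


class TestBatchRemoval:
    def test_single_batch_is_identity(self):
        rng = np.random.default_rng(1)
        matrix = make_matrix(rng.normal(size=(20, 6)))
        batches = pd.Series(["b1"] * 6, index=matrix.columns)
        np.testing.assert_allclose(
            remove_batch_effects(matrix, batches).to_numpy(), matrix.to_numpy(), atol=1e-12
        )

    def test_constant_offset_between_batches_removed(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(30, 4))
        matrix = make_matrix(np.hstack([base, base + 2.0]))
        batches = pd.Series(["A"] * 4 + ["B"] * 4, index=matrix.columns)
        out = remove_batch_effects(matrix, batches)
        mean_a = out.iloc[:, :4].mean(axis=1)
        mean_b = out.iloc[:, 4:].mean(axis=1)
        np.testing.assert_allclose(mean_a, mean_b, atol=1e-12)

    def test_grand_mean_preserved(self):
        rng = np.random.default_rng(3)
        matrix = make_matrix(rng.normal(size=(40, 9)))
        batches = pd.Series(["A", "B", "C"] * 3, index=matrix.columns)
        out = remove_batch_effects(matrix, batches)
        np.testing.assert_allclose(out.mean(axis=1), matrix.mean(axis=1), atol=1e-12)

    def test_unknown_sample_in_batch_map_rejected(self):
        matrix = make_matrix([[1.0, 2.0]])
        batches = pd.Series(["A", "A"], index=["s1", "sX"])
        with pytest.raises(DataError):
            remove_batch_effects(matrix, batches)

    def test_balanced_batches_leave_planted_fisher_ratios_unchanged(self):
        """Batch offsets balanced across classes cancel out of planted-gene FRs."""
        cfg = SimConfig(
            n_genes=300, n_class1=60, n_class2=120, n_planted=30,
            effect_size=1.0, sigma_within=0.7, n_batches=3, batch_sd=0.0, seed=6,
        )
        ds = generate_dataset(cfg)
        clean_fr = score_genes(ds.matrix, ds.labels)["fisher_ratio"]
        # add strong batch offsets, then remove them
        offsets = {"B1": 1.5, "B2": -1.0, "B3": 0.4}
        noisy = ds.matrix.add(ds.batch_assignment.map(offsets), axis=1)
        corrected_fr = score_genes(
            remove_batch_effects(noisy, ds.batch_assignment), ds.labels
        )["fisher_ratio"]
        planted = sorted(ds.planted_genes)
        ratio = corrected_fr[planted].mean() / clean_fr[planted].mean()
        assert abs(ratio - 1.0) < 0.1


class TestDifferentialExpression:
    def test_equal_group_means_give_p_one(self):
        matrix = make_matrix([[1, 3, 1, 3]])
        labels = make_labels(["a", "a", "b", "b"])
        res = differential_expression(matrix, labels)
        assert res.loc["g1", "p_value"] == pytest.approx(1.0)

    def test_textbook_anova_arithmetic(self):
        # {1,2,3} vs {4,5,6}: SSB = 13.5, SSW = 4, F = 13.5 / (4/4) = 13.5 on (1, 4) df
        matrix = make_matrix([[1, 2, 3, 4, 5, 6]])
        labels = make_labels(["a"] * 3 + ["b"] * 3)
        res = differential_expression(matrix, labels)
        grand = 3.5
        ssb = 3 * (2 - grand) ** 2 + 3 * (5 - grand) ** 2
        ssw = sum((v - 2) ** 2 for v in (1, 2, 3)) + sum((v - 5) ** 2 for v in (4, 5, 6))
        f = (ssb / 1) / (ssw / 4)
        assert f == 13.5
        assert res.loc["g1", "p_value"] == pytest.approx(scipy.stats.f.sf(f, 1, 4), rel=1e-12)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(12)
        matrix = make_matrix(rng.normal(size=(50, 10)))
        labels = make_labels(["a"] * 4 + ["b"] * 6)
        res = differential_expression(matrix, labels)
        for g in matrix.index[:10]:
            ref = scipy.stats.f_oneway(matrix.loc[g][:4], matrix.loc[g][4:])
            assert res.loc[g, "p_value"] == pytest.approx(ref.pvalue, rel=1e-9)

    def test_benjamini_hochberg_step_up_rule(self):
        # hand application of the step-up rule: q_(i) = min_{j>=i} p_(j) * m / j
        def step_up(pvals):
            m = len(pvals)
            order = np.argsort(pvals)
            q = np.empty(m)
            running = 1.0
            for pos in range(m - 1, -1, -1):
                i = order[pos]
                running = min(running, pvals[i] * m / (pos + 1))
                q[i] = running
            return q

        p = [0.01, 0.02, 0.03, 0.04]
        np.testing.assert_allclose(step_up(p), [0.04, 0.04, 0.04, 0.04])
        # the module's q-values follow the same rule on real data
        rng = np.random.default_rng(44)
        matrix = make_matrix(rng.normal(size=(40, 8)))
        labels = make_labels(["a"] * 4 + ["b"] * 4)
        res = differential_expression(matrix, labels)
        np.testing.assert_allclose(res["fdr_q"], step_up(res["p_value"].to_numpy()), atol=1e-12)

    def test_degenerate_zero_variance_unequal_means(self):
        matrix = make_matrix([[1, 1, 2, 2], [3, 3, 3, 3]])
        labels = make_labels(["a", "a", "b", "b"])
        res = differential_expression(matrix, labels)
        assert 0 < res.loc["g1", "p_value"] < 1e-300
        assert res.loc["g2", "p_value"] == 1.0

    def test_significance_flag_matches_q_threshold(self, small_dataset):
        res = differential_expression(small_dataset.matrix, small_dataset.labels)
        assert ((res["fdr_q"] < 0.05) == res["significant"]).all()
        assert (res["fdr_q"] >= res["p_value"] - 1e-15).all()
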