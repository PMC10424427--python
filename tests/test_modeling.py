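"""Target binarization, LASSO-logistic fitting, tuning and nested CV."""

import numpy as np
import pytest

from radgroup.fixtures import TableSpec, make_feature_table
from radgroup.modeling import (
    CvConfig,
    binarize_target,
    fit_final_model,
    fit_lr_lasso,
    nested_cv_evaluate,
    permutation_test,
    tune_inner,
    zscore_fit_apply,
)
from radgroup.selection import CfrConfig


def prox_lasso_logistic(x, y, lam, iters=300_000, lr=0.05):
    """Independent proximal-gradient solver for (1/n)·logloss + λ‖β‖₁."""
    n, p = x.shape
    b, b0 = np.zeros(p), 0.0
    for _ in range(iters):
        s = 1.0 / (1.0 + np.exp(-(x @ b + b0)))
        b_new = b - lr * (x.T @ (s - y) / n)
        b0 = b0 - lr * (s - y).mean()
        b = np.sign(b_new) * np.maximum(np.abs(b_new) - lr * lam, 0.0)
    return b, b0


class TestBinarize:
    def test_median_rule_even_distinct(self):
        y = binarize_target([1.0, 2.0, 3.0, 4.0], "median")
        assert y.mean() == 0.5
        np.testing.assert_array_equal(y, [0, 0, 1, 1])

    def test_heavy_ties_not_fifty_percent(self):
        y = binarize_target([1, 1, 1, 1, 1, 2, 3], "median")
        assert y.mean() != 0.5

    def test_stage_rule(self):
        np.testing.assert_array_equal(
            binarize_target([1, 2, 3, 4, 2, 4], "stage"), [0, 0, 1, 1, 0, 1]
        )

    def test_one_vs_all(self):
        y = binarize_target(np.array(["linear", "branched", "linear"]),
                            "one_vs_all", positive_label="linear")
        np.testing.assert_array_equal(y, [1, 0, 1])

    def test_constant_errors(self):
        with pytest.raises(ValueError, match="constant"):
            binarize_target([2.0, 2.0, 2.0], "median")


class TestZscore:
    def test_train_columns_standardized(self):
        rng = np.random.default_rng(0)
        train, test = rng.normal(3, 5, (30, 4)), rng.normal(3, 5, (10, 4))
        ztr, zte, std = zscore_fit_apply(train, test)
        np.testing.assert_allclose(ztr.mean(0), 0, atol=1e-10)
        np.testing.assert_allclose(ztr.std(0), 1, atol=1e-10)

    def test_constant_column_dropped(self):
        rng = np.random.default_rng(1)
        train = rng.normal(size=(20, 3))
        train[:, 1] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            ztr, _, std = zscore_fit_apply(train, train)
        assert ztr.shape[1] == 2
        np.testing.assert_array_equal(std.kept_cols, [0, 2])

    def test_test_rows_never_influence_params(self):
        rng = np.random.default_rng(2)
        train, test = rng.normal(size=(25, 3)), rng.normal(size=(5, 3))
        _, _, std_a = zscore_fit_apply(train, test)
        test_perturbed = test + 100.0
        _, _, std_b = zscore_fit_apply(train, test_perturbed)
        np.testing.assert_array_equal(std_a.mean, std_b.mean)
        np.testing.assert_array_equal(std_a.sd, std_b.sd)


class TestLasso:
    @staticmethod
    def fixed_dataset():
        rng = np.random.default_rng(1)
        x = rng.normal(size=(20, 3))
        eta = x[:, 0] - 0.5 * x[:, 1]
        y = (rng.random(20) < 1 / (1 + np.exp(-eta))).astype(int)
        xs = (x - x.mean(0)) / x.std(0)
        return xs, y

    def test_full_shrinkage_at_large_lambda(self):
        xs, y = self.fixed_dataset()
        coef, _ = fit_lr_lasso(xs, y, lam=10.0)
        np.testing.assert_array_equal(coef, 0.0)

    def test_sign_matches_association(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(200, 2))
        y = (rng.random(200) < 1 / (1 + np.exp(-2 * x[:, 0]))).astype(int)
        xs = (x - x.mean(0)) / x.std(0)
        coef, _ = fit_lr_lasso(xs, y, lam=0.01)
        assert coef[0] > 0

    def test_matches_proximal_gradient_oracle(self):
        xs, y = self.fixed_dataset()
        coef, b0 = fit_lr_lasso(xs, y, lam=0.1)
        ref_coef, ref_b0 = prox_lasso_logistic(xs, y, lam=0.1)
        np.testing.assert_allclose(coef, ref_coef, atol=1e-4)
        assert b0 == pytest.approx(ref_b0, abs=1e-3)

    def test_single_class_errors(self):
        xs, _ = self.fixed_dataset()
        with pytest.raises(ValueError):
            fit_lr_lasso(xs, np.zeros(20, dtype=int), lam=0.1)

    def test_sparsity_monotone_in_lambda(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(60, 10))
        y = (rng.random(60) < 1 / (1 + np.exp(-x[:, 0] + x[:, 3]))).astype(int)
        xs = (x - x.mean(0)) / x.std(0)
        nnz = [
            int((fit_lr_lasso(xs, y, lam)[0] != 0).sum())
            for lam in (0.001, 0.01, 0.05, 0.1, 0.5, 1.0)
        ]
        assert nnz == sorted(nnz, reverse=True)


class TestTuneInner:
    def test_single_candidate_returned_unchanged(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(40, 3))
        y = (rng.random(40) < 0.5).astype(int)
        group, lam = tune_inner(x, y, {"all": np.arange(3)}, (0.2,), 3, seed=0)
        assert (group, lam) == ("all", 0.2)

    def test_informative_group_recovered(self):
        spec = TableSpec(
            n_samples=200, n_shape=3, n_firstorder=3, n_texture=4,
            informative_group="firstorder", n_signal=3, effect=1.5, seed=9,
        )
        table, y = make_feature_table(spec)
        keys = table.keys()
        from radgroup.selection import enumerate_candidate_groups

        groups = enumerate_candidate_groups(keys)
        index = {k: i for i, k in enumerate(keys)}
        cols = {n: np.array([index[k] for k in m]) for n, m in groups.groups.items()}
        wins = []
        for seed in range(10):
            g, _ = tune_inner(table.values, y, cols, (0.01, 0.05, 0.2), 3, seed=seed)
            wins.append(g)
        frac_contains = np.mean(["firstorder" in g or g == "all" for g in wins])
        assert frac_contains >= 0.9
        assert max(set(wins), key=wins.count) == "firstorder"

    def test_tie_break_prefers_smaller_group_then_larger_lambda(self):
        # constant-score degenerate case: every candidate ties at AUROC 0.5
        rng = np.random.default_rng(6)
        x = np.repeat(rng.normal(size=(1, 4)), 30, axis=0) + 0.0
        x += rng.normal(scale=1e-12, size=x.shape)  # avoid constant-drop path
        y = np.tile([0, 1], 15)
        cols = {"big": np.arange(4), "small": np.arange(2)}
        group, lam = tune_inner(x, y, cols, (0.1, 1.0), 3, seed=0)
        assert group == "small" and lam == 1.0


class TestNestedCv:
    def test_split_count_law(self, small_table_spec):
        table, y = make_feature_table(small_table_spec)
        config = CvConfig(outer_folds=5, outer_repeats=4, lambda_grid=(0.05, 0.2), seed=0)
        result = nested_cv_evaluate(table, y, config, "conventional")
        assert len(result.per_split_auroc) == 20
        assert len(result.per_split_fit) == 20
        assert result.mean_auroc == pytest.approx(np.mean(result.per_split_auroc))

    def test_perfect_feature_gives_high_auroc(self):
        spec = TableSpec(n_samples=80, n_shape=2, n_firstorder=2, n_texture=2,
                         informative_group="firstorder", effect=0.0, seed=10)
        table, _ = make_feature_table(spec)
        # plant a perfectly separating feature
        y = (table.values[:, 3] > 0).astype(int)
        config = CvConfig(outer_repeats=1, lambda_grid=(0.01,), seed=0)
        result = nested_cv_evaluate(table, y, config, "conventional")
        assert result.mean_auroc >= 0.99

    def test_null_labels_near_chance(self):
        spec = TableSpec(n_samples=150, n_shape=4, n_firstorder=4, n_texture=6,
                         effect=0.0, seed=11)
        table, y = make_feature_table(spec)
        rng = np.random.default_rng(0)
        config = CvConfig(outer_repeats=4, lambda_grid=(0.05, 0.2), seed=1)
        result = nested_cv_evaluate(table, rng.permutation(y), config, "conventional")
        assert 0.4 < result.mean_auroc < 0.6

    def test_deterministic_given_seed(self, small_table_spec):
        table, y = make_feature_table(small_table_spec)
        config = CvConfig(outer_repeats=2, lambda_grid=(0.05, 0.2), seed=5)
        r1 = nested_cv_evaluate(table, y, config, "proposed")
        r2 = nested_cv_evaluate(table, y, config, "proposed")
        assert r1.per_split_auroc == r2.per_split_auroc
        assert [f.selected_group for f in r1.per_split_fit] == [
            f.selected_group for f in r2.per_split_fit
        ]

    def test_conventional_mode_fixes_group_to_all(self, small_table_spec):
        table, y = make_feature_table(small_table_spec)
        config = CvConfig(outer_repeats=1, lambda_grid=(0.05, 0.2), seed=2)
        result = nested_cv_evaluate(table, y, config, "conventional")
        assert {f.selected_group for f in result.per_split_fit} == {"all"}

    def test_nonzero_coefficients_confined_to_selected_group(self, small_table_spec):
        table, y = make_feature_table(small_table_spec)
        config = CvConfig(outer_repeats=1, lambda_grid=(0.05,), seed=3,
                          cfr=CfrConfig(mode="hierarchical"))
        result = nested_cv_evaluate(table, y, config, "proposed")
        from radgroup.selection import enumerate_candidate_groups

        for fit in result.per_split_fit:
            allowed = set(fit.feature_keys)
            assert set(fit.coefficients) <= allowed


class TestPermutationTest:
    config = CvConfig(outer_folds=5, outer_repeats=1, lambda_grid=(0.05, 0.2), seed=0)

    def test_p_floor_when_observed_beats_every_null(self):
        spec = TableSpec(n_samples=100, n_shape=2, n_firstorder=2, n_texture=2,
                         informative_group="firstorder", effect=3.0, seed=12)
        table, y = make_feature_table(spec)
        perm = permutation_test(table, y, self.config, n_perm=19, seed=1,
                                mode="conventional")
        assert perm.p_value == pytest.approx(1 / 20)

    def test_same_seed_identical_p(self, small_table_spec):
        table, y = make_feature_table(small_table_spec)
        p1 = permutation_test(table, y, self.config, n_perm=19, seed=4,
                              mode="conventional")
        p2 = permutation_test(table, y, self.config, n_perm=19, seed=4,
                              mode="conventional")
        assert p1.p_value == p2.p_value
        assert p1.null_aurocs == p2.null_aurocs

    def test_minimum_permutations_enforced(self, small_table_spec):
        table, y = make_feature_table(small_table_spec)
        with pytest.raises(ValueError):
            permutation_test(table, y, self.config, n_perm=5, seed=0)


class TestFinalModel:
    def test_separable_toy_data_has_nonzero_coefficient(self):
        spec = TableSpec(n_samples=60, n_shape=2, n_firstorder=2, n_texture=2,
                         effect=0.0, seed=13)
        table, _ = make_feature_table(spec)
        y = (table.values[:, 0] > 0).astype(int)  # MeshVolume separates
        config = CvConfig(outer_repeats=1, lambda_grid=(0.01, 0.1), seed=0,
                          cfr=CfrConfig(mode="hierarchical"))
        fit = fit_final_model(table, y, config, "proposed")
        assert fit.n_nonzero >= 1

    def test_conventional_final_group_is_all(self, small_table_spec):
        table, y = make_feature_table(small_table_spec)
        config = CvConfig(outer_repeats=1, lambda_grid=(0.05,), seed=1)
        fit = fit_final_model(table, y, config, "conventional")
        assert fit.selected_group == "all"

    def test_signal_group_modal_over_seeds(self):
        wins = []
        for seed in range(8):
            spec = TableSpec(n_samples=150, n_shape=3, n_firstorder=3, n_texture=4,
                             informative_group="shape", n_signal=3, effect=1.5,
                             seed=seed)
            table, y = make_feature_table(spec)
            config = CvConfig(outer_repeats=1, lambda_grid=(0.02, 0.1), seed=seed,
                              cfr=CfrConfig(mode="hierarchical"))
            fit = fit_final_model(table, y, config, "proposed")
            wins.append(fit.selected_group)
        modal = max(set(wins), key=wins.count)
        assert "shape" in modal or modal == "all"
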