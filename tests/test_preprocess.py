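import numpy as np
import pytest

from daedsr import (
    PreprocessState,
    RegistryPreprocessor,
    TrialTable,
    drop_duplicates,
    drop_sparse_columns,
    knn_impute,
    normalize_numeric,
    smote_balance,
    split_train_test,
)


def _table(cov, time, event, numeric=()):
    cov = np.asarray(cov, dtype=float)
    names = [f"c{i}" for i in range(cov.shape[1])]
    numeric_names = [names[i] for i in numeric]
    return TrialTable(cov, time, event, names, numeric_names)


class TestDropDuplicates:
    def test_no_duplicates_identity(self):
        t = _table([[1, 0], [0, 1]], [1, 2], [1, 0])
        assert drop_duplicates(t).n == 2

    def test_exact_duplicates_collapse(self):
        cov = np.vstack([np.eye(2)] * 5)  # 10 rows, many duplicates
        t = _table(cov, [1, 2] * 5, [1, 0] * 5)
        out = drop_duplicates(t)
        assert out.n == 2

    def test_rows_differing_only_in_time_kept(self):
        t = _table([[1, 0], [1, 0]], [1, 2], [1, 1])
        assert drop_duplicates(t).n == 2


class TestDropSparseColumns:
    def test_strictly_greater_than_threshold_dropped(self):
        cov = np.ones((10, 3))
        cov[:9, 0] = np.nan  # 90% missing -> dropped
        cov[:8, 1] = np.nan  # exactly 80% -> kept
        t = _table(cov, np.arange(1, 11), np.ones(10, int))
        out, dropped = drop_sparse_columns(t, 0.8)
        assert dropped == ["c0"]
        assert out.column_names == ["c1", "c2"]

    def test_fully_observed_table_untouched(self, small_registry):
        _, table = small_registry
        out, dropped = drop_sparse_columns(table)
        assert dropped == [] and out.p == table.p

    def test_all_columns_dropped_is_error(self):
        # every column 50% missing (> 0.4) but each row keeps one
        # observed cell, so the table itself is valid
        cov = np.ones((10, 3))
        cov[:5, 0] = np.nan
        cov[5:, 1] = np.nan
        cov[:5, 2] = np.nan
        t = _table(cov, np.arange(1, 11), np.ones(10, int))
        with pytest.raises(ValueError, match="all covariate columns"):
            drop_sparse_columns(t, 0.4)


class TestKnnImpute:
    def test_no_missing_is_identity(self, clean_registry):
        _, table = clean_registry
        out = knn_impute(table)
        np.testing.assert_array_equal(out.covariates, table.covariates)

    def test_hand_computed_neighbor_mean(self):
        # rows 0,1 are the two nearest neighbors of row 3 in the second
        # column, so the missing value is the mean of their first column
        cov = np.array([[1.0, 0.0], [1.0, 0.0], [9.0, 4.0], [np.nan, 0.1]])
        t = _table(cov, [1, 2, 3, 4], [1, 1, 1, 1], numeric=(0, 1))
        out = knn_impute(t, k=2)
        assert out.covariates[3, 0] == pytest.approx(1.0)

    def test_binary_imputation_lands_in_01(self):
        rng = np.random.default_rng(0)
        cov = rng.integers(0, 2, size=(30, 3)).astype(float)
        cov[rng.random((30, 3)) < 0.2] = np.nan
        cov[np.isnan(cov).all(axis=1), 0] = 1.0
        t = _table(cov, np.arange(1, 31), np.ones(30, int))
        out = knn_impute(t, k=5)
        assert set(np.unique(out.covariates)) <= {0.0, 1.0}

    def test_idempotent(self, small_registry):
        _, table = small_registry
        once = knn_impute(table)
        twice = knn_impute(once)
        np.testing.assert_array_equal(once.covariates, twice.covariates)

    def test_imputed_values_within_observed_range(self, small_registry):
        _, table = small_registry
        out = knn_impute(table)
        miss = np.isnan(table.covariates)
        for j in range(table.p):
            col = table.covariates[:, j]
            obs = col[~np.isnan(col)]
            filled = out.covariates[miss[:, j], j]
            assert np.all(filled >= obs.min() - 1e-12)
            assert np.all(filled <= obs.max() + 1e-12)

    def test_fully_missing_column_is_error(self):
        cov = np.array([[1.0, np.nan], [2.0, np.nan]])
        t = _table(cov, [1, 2], [1, 1])
        with pytest.raises(ValueError, match="drop_sparse_columns"):
            knn_impute(t)


class TestNormalizeNumeric:
    def test_zscore_closed_form(self):
        t = _table([[1.0], [2.0], [3.0]], [1, 2, 3], [1, 1, 1], numeric=(0,))
        state = PreprocessState()
        out = normalize_numeric(t, fit=True, state=state)
        np.testing.assert_allclose(
            out.covariates[:, 0], [-1.224745, 0.0, 1.224745], atol=1e-6
        )

    def test_binary_columns_untouched(self):
        t = _table([[1.0, 1.0], [0.0, 2.0]], [1, 2], [1, 1], numeric=(1,))
        out = normalize_numeric(t, fit=True, state=PreprocessState())
        np.testing.assert_array_equal(out.covariates[:, 0], [1.0, 0.0])

    def test_training_stats_reused_on_new_data(self):
        state = PreprocessState()
        train = _table([[0.0], [10.0]], [1, 2], [1, 1], numeric=(0,))
        normalize_numeric(train, fit=True, state=state)
        test = _table([[5.0], [6.0]], [1, 2], [1, 1], numeric=(0,))
        out = normalize_numeric(test, fit=False, state=state)
        # transformed with the training mean 5, sd 5 — not with self stats
        np.testing.assert_allclose(out.covariates[:, 0], [0.0, 0.2])

    def test_zero_variance_column_is_error(self):
        t = _table([[1.0], [1.0]], [1, 2], [1, 1], numeric=(0,))
        with pytest.raises(ValueError, match="c0"):
            normalize_numeric(t, fit=True, state=PreprocessState())


class TestSmote:
    def _imbalanced(self, n_min=10, n_maj=40, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((n_min + n_maj, 4))
        e = np.array([0] * n_min + [1] * n_maj)
        t = rng.exponential(100, n_min + n_maj) + 1
        return x, e, t

    def test_balances_to_equal_counts(self):
        x, e, t = self._imbalanced()
        x2, e2, t2 = smote_balance(x, e, t, seed=1)
        assert len(x2) == 80 and (e2 == 0).sum() == (e2 == 1).sum() == 40
        np.testing.assert_array_equal(x2[:50], x)  # originals verbatim

    def test_already_balanced_unchanged(self):
        x, e, t = self._imbalanced(25, 25)
        x2, e2, t2 = smote_balance(x, e, t, seed=1)
        assert len(x2) == 50

    def test_identical_parents_give_identical_child(self):
        x = np.array([[1.0, 2.0]] * 2 + [[0.0, 0.0]] * 6)
        e = np.array([0, 0, 1, 1, 1, 1, 1, 1])
        t = np.arange(1.0, 9.0)
        x2, e2, t2 = smote_balance(x, e, t, seed=3)
        np.testing.assert_allclose(x2[8:], [[1.0, 2.0]] * 4)

    def test_synthetic_rows_on_minority_segments(self):
        x, e, t = self._imbalanced()
        x2, e2, t2 = smote_balance(x, e, t, seed=5)
        minority = x[e == 0]
        for row in x2[50:]:
            on_segment = False
            for a in range(len(minority)):
                for b in range(len(minority)):
                    if a == b:
                        continue
                    d = minority[b] - minority[a]
                    v = row - minority[a]
                    denom = d @ d
                    u = (v @ d) / denom if denom > 0 else 0.0
                    if -1e-9 <= u <= 1 + 1e-9 and np.allclose(
                        v, u * d, atol=1e-9
                    ):
                        on_segment = True
                        break
                if on_segment:
                    break
            assert on_segment

    def test_reproducible_for_fixed_seed(self):
        x, e, t = self._imbalanced()
        a = smote_balance(x, e, t, seed=9)
        b = smote_balance(x, e, t, seed=9)
        for u, v in zip(a, b):
            np.testing.assert_array_equal(u, v)

    def test_singleton_minority_is_error(self):
        x, e, t = self._imbalanced(1, 5)
        with pytest.raises(ValueError, match="size 1"):
            smote_balance(x, e, t)


class TestSplit:
    def test_registry_scale_split(self):
        t = _table(np.ones((819, 1)), np.arange(1, 820), np.ones(819, int))
        tr, te = split_train_test(t, 0.8, seed=0)
        assert (tr.n, te.n) == (655, 164)

    def test_same_seed_same_split(self, small_registry):
        _, table = small_registry
        a = split_train_test(table, 0.7, seed=5)
        b = split_train_test(table, 0.7, seed=5)
        np.testing.assert_array_equal(a[0].time, b[0].time)

    def test_even_split(self):
        t = _table(np.ones((10, 1)), np.arange(1, 11), np.ones(10, int))
        tr, te = split_train_test(t, 0.5, seed=1)
        assert (tr.n, te.n) == (5, 5)


class TestRegistryPreprocessor:
    def test_fit_transform_pipeline(self, small_registry):
        _, table = small_registry
        tr_raw, te_raw = split_train_test(table, 0.8, seed=0)
        prep = RegistryPreprocessor().fit(tr_raw)
        train, test = prep.train_table_, prep.transform(te_raw)
        assert not np.isnan(train.covariates).any()
        assert not np.isnan(test.covariates).any()
        # numeric columns standardized with training stats
        for name in train.numeric_column_names:
            assert name in prep.state_.numeric_stats

    def test_transform_without_fit_is_error(self, small_registry):
        _, table = small_registry
        with pytest.raises(ValueError, match="not fitted"):
            RegistryPreprocessor().transform(table)

    def test_sklearn_param_interface(self):
        prep = RegistryPreprocessor(k_impute=3)
        assert prep.get_params()["k_impute"] == 3
        prep.set_params(k_impute=7)
        assert prep.k_impute == 7
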