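import numpy as np
import pandas as pd
import pytest
from scipy import stats

import oracles
from bactipred import mdg_select, pearson_filter, rfe, roc_auc, ttest_filter
from bactipred.selection import default_size_grid


def test_identical_columns_drop_exactly_one():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(50)
    m = pd.DataFrame({"a": x, "b": x, "c": rng.standard_normal(50)})
    res = pearson_filter(m, 0.9)
    assert len(res.dropped) == 1
    assert {res.dropped[0][0], res.dropped[0][1]} == {"a", "b"}
    assert "c" in res.retained


def test_orthogonal_columns_all_retained():
    rng = np.random.default_rng(1)
    m = pd.DataFrame(rng.standard_normal((200, 10)), columns=[f"f{i}" for i in range(10)])
    res = pearson_filter(m, 0.9)
    assert res.retained == list(m.columns) and not res.dropped


def test_constant_columns_dropped_and_logged():
    rng = np.random.default_rng(2)
    m = pd.DataFrame({"k": np.ones(30), "x": rng.standard_normal(30)})
    res = pearson_filter(m)
    assert res.constant_dropped == ["k"] and res.retained == ["x"]


def test_pearson_filter_idempotent():
    rng = np.random.default_rng(3)
    base = rng.standard_normal((80, 6))
    m = pd.DataFrame(
        np.column_stack([base, base[:, 0] + 0.01 * rng.standard_normal(80)]),
        columns=[f"f{i}" for i in range(7)],
    )
    first = pearson_filter(m)
    second = pearson_filter(m[first.retained])
    assert not second.dropped
    assert second.retained == first.retained


def test_pearson_filter_single_row_errors():
    with pytest.raises(ValueError):
        pearson_filter(pd.DataFrame({"a": [1.0]}))


def test_retained_pairwise_correlation_below_cutoff():
    rng = np.random.default_rng(4)
    z = rng.standard_normal((100, 3))
    cols = {f"c{i}": z[:, i % 3] + 0.2 * rng.standard_normal(100) for i in range(9)}
    m = pd.DataFrame(cols)
    res = pearson_filter(m, 0.8)
    corr = m[res.retained].corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    assert (corr < 0.8).all()


# ---------------------------------------------------------------------------
# t-test filter
# ---------------------------------------------------------------------------

def test_welch_closed_form_example():
    m = pd.DataFrame({"f": [1.0, 2.0, 3.0, 6.0, 7.0, 8.0]})
    y = np.array([-1, -1, -1, 1, 1, 1])
    res = ttest_filter(m, y, alpha=0.05)
    row = res.table.loc["f"]
    # class means 2 vs 7, unit variances: t = 5 / sqrt(2/3), df = 4
    assert abs(row["t"]) == pytest.approx(6.1237, abs=1e-3)
    assert row["p"] == pytest.approx(0.0036, abs=2e-4)
    assert row["retained"]


def test_constant_feature_p_one_and_dropped():
    m = pd.DataFrame({"k": np.ones(10), "s": np.r_[np.zeros(5), np.ones(5)]})
    y = np.array([1] * 5 + [-1] * 5)
    res = ttest_filter(m, y)
    assert res.table.loc["k", "p"] == 1.0 and "k" not in res.retained
    assert "s" in res.retained


def test_welch_matches_textbook_on_random_data():
    rng = np.random.default_rng(8)
    m = pd.DataFrame(rng.standard_normal((40, 25)), columns=[f"f{i}" for i in range(25)])
    y = np.array([1] * 22 + [-1] * 18)
    res = ttest_filter(m, y)
    for i, c in enumerate(m.columns):
        t, p = stats.ttest_ind(m[c][y == 1], m[c][y == -1], equal_var=False)
        assert res.table.loc[c, "t"] == pytest.approx(t, abs=1e-10)
        assert res.table.loc[c, "p"] == pytest.approx(p, abs=1e-10)


def test_ttest_needs_two_classes():
    with pytest.raises(ValueError):
        ttest_filter(pd.DataFrame({"f": np.ones(4)}), np.ones(4))


# ---------------------------------------------------------------------------
# MDG ranking
# ---------------------------------------------------------------------------

def test_perfect_separator_ranks_first_across_seeds():
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(1000 + seed)
        y = np.array([1] * 30 + [-1] * 30)
        X = rng.standard_normal((60, 10))
        X[:, 0] = y * 3.0 + 0.1 * rng.standard_normal(60)
        m = pd.DataFrame(X, columns=[f"f{i}" for i in range(10)])
        r = mdg_select(m, y, n_trees=100, seed=seed)
        hits += r.ranked[0] == "f0"
    assert hits >= 19


def test_top_k_rule_returns_exactly_k():
    rng = np.random.default_rng(9)
    m = pd.DataFrame(rng.standard_normal((50, 60)), columns=[f"f{i}" for i in range(60)])
    y = np.array([1] * 25 + [-1] * 25)
    r = mdg_select(m, y, n_trees=50, rule="top-k", top_k=44, seed=0)
    assert len(r.selected) == 44


def test_mdg_scores_nonnegative_and_rank_is_permutation():
    rng = np.random.default_rng(10)
    m = pd.DataFrame(rng.standard_normal((40, 8)), columns=[f"f{i}" for i in range(8)])
    y = np.array([1] * 20 + [-1] * 20)
    r = mdg_select(m, y, n_trees=50, seed=1)
    assert (r.scores >= 0).all()
    assert sorted(r.ranked) == sorted(m.columns)


# ---------------------------------------------------------------------------
# ROC-AUC
# ---------------------------------------------------------------------------

def test_auc_trivial_cases():
    assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, -1, -1]) == 1.0
    assert roc_auc([0.5, 0.5, 0.5, 0.5], [1, 1, -1, -1]) == 0.5


def test_auc_pairwise_example():
    assert roc_auc([0.9, 0.8, 0.4, 0.3], [1, -1, 1, -1]) == pytest.approx(0.75)


def test_auc_matches_bruteforce_pair_count():
    rng = np.random.default_rng(11)
    scores = rng.random(30)
    labels = rng.choice([1, -1], 30)
    if len(np.unique(labels)) == 2:
        assert roc_auc(scores, labels) == pytest.approx(
            oracles.naive_auc(scores, labels)
        )


def test_auc_single_class_errors():
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.9], [1, 1])


# ---------------------------------------------------------------------------
# RFE
# ---------------------------------------------------------------------------

def test_size_grid_dense_then_geometric():
    assert default_size_grid(5) == [1, 2, 3, 4, 5]
    grid = default_size_grid(140)
    assert grid[0] == 1 and grid[-1] == 140 and len(grid) <= 21


def test_informative_feature_always_selected(gaussian_features):
    X, y = gaussian_features
    m = X[["inf_0"] + [f"noise_{i}" for i in range(9)]]
    res = rfe(m, y, estimator="svm", sizes=[1, 2, 5, 10], cv_folds=5, cv_repeats=1, seed=0)
    assert "inf_0" == res.ranking[0]
    assert "inf_0" in res.selected


def test_rfe_selected_is_prefix_of_ranking(gaussian_features):
    X, y = gaussian_features
    res = rfe(X.iloc[:, :20], y, estimator="rf", sizes=[2, 5, 10],
              cv_folds=5, cv_repeats=1, seed=3, n_trees=50)
    assert res.selected == res.ranking[: res.best_size]
    assert res.best_size in res.sizes
    assert all(0.0 <= a <= 1.0 for a in res.mean_auc)


def test_rfe_shuffled_labels_near_chance(gaussian_features):
    X, y = gaussian_features
    rng = np.random.default_rng(12)
    y_shuf = rng.permutation(y)
    res = rfe(X, y_shuf, estimator="svm", sizes=[10, 50, 100],
              cv_folds=5, cv_repeats=2, seed=0)
    assert abs(float(np.mean(res.mean_auc)) - 0.5) <= 0.1


def test_rfe_fold_count_checked(gaussian_features):
    X, y = gaussian_features
    idx = list(range(4)) + list(range(60, 64))  # 4 per class
    with pytest.raises(ValueError, match="cv_folds"):
        rfe(X.iloc[idx], y[idx], estimator="svm", sizes=[2], cv_folds=10)
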