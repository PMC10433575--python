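"""Four-stage feature-selection cascade.

1. Pearson correlation filter (|rho| >= 0.9 drops one of the pair),
2. per-feature Welch t-test filter (keep p <= 0.05),
3. mean-decrease-Gini (MDG) ranking from a random forest,
4. recursive feature elimination scored by repeated stratified k-fold
   cross-validated AUC over a grid of subset sizes.

Stages 2 and 3 are alternative branches (the t-test-reduced and MDG-reduced
feature sets); stage 4 refines either with an SVM-RBF or RF assessor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve, Mann-Whitney formulation (ties count 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("roc_auc needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass
class CorrelationFilterResult:
    retained: list[str]
    dropped: list[tuple[str, str, float]]  # (dropped, partner, rho)
    constant_dropped: list[str] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def pearson_filter(matrix: pd.DataFrame, cutoff: float = 0.9) -> CorrelationFilterResult:
    """Drop one member of every feature pair with |rho| >= cutoff.

    Constant columns (rho undefined) are dropped first and reported
    separately.  Among a violating pair, the member with the larger mean
    absolute correlation against all other features is dropped; ties go to
    the later column.  A second pass on the output drops nothing.
    """
    if len(matrix) < 2:
        raise ValueError("correlation filter needs at least 2 rows")
    sd = matrix.std(ddof=0)
    constant = list(matrix.columns[sd == 0.0])
    work = matrix.drop(columns=constant)
    cols = list(work.columns)
    if len(cols) < 2:
        return CorrelationFilterResult(cols, [], constant)
    corr = np.corrcoef(work.to_numpy(), rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    abs_corr = np.abs(corr)
    np.fill_diagonal(abs_corr, 0.0)
    mean_abs = abs_corr.mean(axis=0)

    dropped_idx: set[int] = set()
    dropped: list[tuple[str, str, float]] = []
    n = len(cols)
    for i in range(n):
        if i in dropped_idx:
            continue
        for j in range(i + 1, n):
            if j in dropped_idx or i in dropped_idx:
                continue
            if abs_corr[i, j] >= cutoff:
                loser = j if mean_abs[j] >= mean_abs[i] else i
                winner = i + j - loser
                dropped_idx.add(loser)
                dropped.append((cols[loser], cols[winner], float(corr[i, j])))
    retained = [c for k, c in enumerate(cols) if k not in dropped_idx]
    return CorrelationFilterResult(retained, dropped, constant)


@dataclass
class TTestFilterResult:
    table: pd.DataFrame  # index=feature, columns: t, df, p, retained
    alpha: float

    @property
    def retained(self) -> list[str]:
        return list(self.table.index[self.table["retained"]])


def ttest_filter(matrix: pd.DataFrame, labels, alpha: float = 0.05) -> TTestFilterResult:
    """Welch two-sample t-test per feature; keep features with p <= alpha.

    A feature constant within both classes carries no signal: p = 1 by
    convention and it is dropped.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("ttest_filter needs exactly two classes")
    a = matrix.to_numpy()[labels == classes.max()]
    b = matrix.to_numpy()[labels == classes.min()]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs at least 2 members")
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant columns trigger a scipy precision warning; they are
        # handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, equal_var=False, axis=0)
        t = np.array(res.statistic, dtype=float)
        p = np.array(res.pvalue, dtype=float)
        df = np.array(res.df, dtype=float)
    # nan t-statistic: the feature is identical in both classes (no signal),
    # p = 1 by convention.  An infinite t (zero within-class variance but
    # different means) is maximal signal and keeps its p of 0.
    degenerate = np.isnan(t)
    t[degenerate], p[degenerate], df[degenerate] = 0.0, 1.0, np.nan
    table = pd.DataFrame(
        {"t": t, "df": df, "p": p, "retained": p <= alpha}, index=matrix.columns
    )
    return TTestFilterResult(table, alpha)


@dataclass
class MDGRanking:
    scores: pd.Series  # MDG per feature, input column order
    rule: str
    selected: list[str]

    @property
    def ranked(self) -> list[str]:
        order = np.argsort(-self.scores.to_numpy(), kind="stable")
        return list(self.scores.index[order])


def mdg_select(
    matrix: pd.DataFrame,
    labels,
    n_trees: int = 500,
    rule: str = "above-mean",
    top_k: int | None = None,
    seed: int = 0,
) -> MDGRanking:
    """Rank features by random-forest mean decrease in Gini impurity.

    Default rule keeps features scoring above the mean MDG; rule="top-k"
    keeps exactly top_k (e.g. 44 to match a fixed target dimensionality).
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("mdg_select needs both classes present")
    if matrix.shape[1] < 2:
        raise ValueError("mdg_select needs at least 2 features")
    forest = RandomForestClassifier(
        n_estimators=n_trees, criterion="gini", random_state=seed, n_jobs=1
    )
    forest.fit(matrix.to_numpy(), labels)
    scores = pd.Series(forest.feature_importances_, index=matrix.columns)
    if rule == "above-mean":
        selected = list(scores.index[scores > scores.mean()])
    elif rule == "top-k":
        if top_k is None or top_k < 1 or top_k > len(scores):
            raise ValueError("top-k rule needs 1 <= top_k <= n_features")
        order = np.argsort(-scores.to_numpy(), kind="stable")[:top_k]
        selected = list(scores.index[order])
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return MDGRanking(scores, rule, selected)


@dataclass
class RFEResult:
    sizes: list[int]
    mean_auc: list[float]
    best_size: int
    selected: list[str]
    ranking: list[str]  # all input features, best first
    estimator: str

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"size": self.sizes, "mean_cv_auc": self.mean_auc})


def default_size_grid(n_features: int, max_dense: int = 60, n_points: int = 20) -> list[int]:
    """{1..N} when N <= max_dense, else a geometric grid of n_points plus N."""
    if n_features <= max_dense:
        return list(range(1, n_features + 1))
    grid = np.unique(
        np.round(np.geomspace(1, n_features, n_points)).astype(int)
    ).tolist()
    if n_features not in grid:
        grid.append(n_features)
    return grid


def _make_estimator(kind: str, seed: int, n_trees: int):
    if kind in ("svm", "svm-rbf"):
        return make_pipeline(
            StandardScaler(), SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed)
        )
    if kind in ("rf", "random-forest"):
        return RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    raise ValueError(f"unknown estimator {kind!r}")


def rank_features(matrix: pd.DataFrame, labels, estimator: str, seed: int = 0,
                  n_trees: int = 100) -> list[str]:
    """Feature ranking used inside RFE: RF impurity importance, or for the
    kernel SVM (no native per-feature weight) univariate |AUC - 0.5|."""
    labels = np.asarray(labels)
    if estimator in ("rf", "random-forest"):
        forest = RandomForestClassifier(n_estimators=max(n_trees, 100),
                                        random_state=seed, n_jobs=1)
        forest.fit(matrix.to_numpy(), labels)
        scores = forest.feature_importances_
    else:
        y = labels == labels.max()
        scores = np.array(
            [abs(roc_auc_score(y, matrix[c].to_numpy()) - 0.5) for c in matrix.columns]
        )
    order = np.argsort(-scores, kind="stable")
    return list(matrix.columns[order])


def rfe(
    matrix: pd.DataFrame,
    labels,
    estimator: str = "svm",
    sizes: list[int] | None = None,
    cv_folds: int = 10,
    cv_repeats: int = 5,
    seed: int = 0,
    n_trees: int = 100,
) -> RFEResult:
    """Sweep subset sizes over the feature ranking; score each subset by mean
    repeated-stratified-k-fold cross-validated AUC of the estimator; the best
    size is the argmax (ties to the smaller subset).

    To keep the CV estimate honest, the feature ranking is recomputed inside
    every fold from that fold's training part only (as caret's rfe resampling
    does); the reported ranking and the selected set come from a final
    ranking on the full input.  Under label permutation the per-size mean
    CV-AUC therefore stays near chance.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError("rfe needs exactly two classes")
    if cv_folds > counts.min():
        raise ValueError(
            f"cv_folds={cv_folds} exceeds smallest class count {counts.min()}"
        )
    n = matrix.shape[1]
    if sizes is None:
        sizes = default_size_grid(n)
    sizes = sorted(set(int(s) for s in sizes))
    if not sizes or sizes[0] < 1 or sizes[-1] > n:
        raise ValueError("sizes must be within [1, n_features]")

    X = matrix.to_numpy()
    col_idx = {c: i for i, c in enumerate(matrix.columns)}
    pos_label = classes.max()
    cv = RepeatedStratifiedKFold(n_splits=cv_folds, n_repeats=cv_repeats, random_state=seed)
    fold_aucs: list[list[float]] = [[] for _ in sizes]
    for train_ix, test_ix in cv.split(X, labels):
        fold_rank = rank_features(
            matrix.iloc[train_ix], labels[train_ix], estimator, seed=seed, n_trees=n_trees
        )
        order = np.array([col_idx[c] for c in fold_rank])
        for s_i, size in enumerate(sizes):
            keep = order[:size]
            est = _make_estimator(estimator, seed, n_trees)
            est.fit(X[np.ix_(train_ix, keep)], labels[train_ix])
            X_te = X[np.ix_(test_ix, keep)]
            if hasattr(est, "decision_function"):
                scores = est.decision_function(X_te)
            else:
                pos_col = int(np.where(est.classes_ == pos_label)[0][0])
                scores = est.predict_proba(X_te)[:, pos_col]
            fold_aucs[s_i].append(roc_auc_score(labels[test_ix] == pos_label, scores))
    mean_auc = [float(np.mean(a)) for a in fold_aucs]
    best_idx = int(np.argmax(mean_auc))  # argmax takes the first, i.e. smaller size
    best_size = sizes[best_idx]
    ranking = rank_features(matrix, labels, estimator, seed=seed, n_trees=n_trees)
    return RFEResult(sizes, mean_auc, best_size, ranking[:best_size], ranking, estimator)


@dataclass
class SelectionReport:
    """Cumulative record of the cascade: surviving names plus per-stage stats."""

    correlation: CorrelationFilterResult
    branch: str  # "ttest" or "mdg"
    ttest: TTestFilterResult | None
    mdg: MDGRanking | None
    rfe: RFEResult
    selected: list[str]

    def stage_counts(self) -> dict[str, int]:
        counts = {"input": len(self.correlation.retained) + len(self.correlation.dropped)
                  + len(self.correlation.constant_dropped),
                  "after_correlation": len(self.correlation.retained)}
        if self.ttest is not None:
            counts["after_ttest"] = len(self.ttest.retained)
        if self.mdg is not None:
            counts["after_mdg"] = len(self.mdg.selected)
        counts["after_rfe"] = len(self.selected)
        return counts

    def to_frame(self) -> pd.DataFrame:
        """Per-feature table: stage statistics and kept/dropped flags."""
        all_names = (
            self.correlation.retained
            + [d for d, _, _ in self.correlation.dropped]
            + self.correlation.constant_dropped
        )
        df = pd.DataFrame(index=pd.Index(sorted(all_names), name="feature"))
        df["passed_correlation"] = df.index.isin(self.correlation.retained)
        if self.ttest is not None:
            df = df.join(self.ttest.table[["t", "p"]])
        if self.mdg is not None:
            df = df.join(self.mdg.scores.rename("mdg"))
        df["selected"] = df.index.isin(self.selected)
        return df
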