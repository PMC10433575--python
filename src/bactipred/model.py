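"""Model/Results surface over the full prediction pipeline.

`BacteriocinModel` holds a labeled sequence dataset plus configuration;
`fit()` runs redundancy reduction, class balancing, the stratified split,
descriptor extraction, the feature-selection cascade and classifier tuning,
and returns a `BacteriocinResults` carrying the trained bundles, per-branch
selection reports, held-out evaluations and a printable summary table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import selection as sel
from .descriptors import DescriptorConfig, build_feature_matrix, labels_vector
from .evaluation import MetricsReport, confusion, identity_baseline_sweep, metrics
from .models import RfGrid, SvmGrid, TrainedClassifier, tune_and_train
from .sequence_io import (
    LabeledDataset,
    NEGATIVE,
    POSITIVE,
    balance_by_subsampling,
    read_fasta,
    reduce_redundancy,
    stratified_split,
)

#: the four cascade branches: reduced set ("mdg" or "ttest") x RFE assessor
DEFAULT_BRANCHES = ("mdg-rf", "mdg-svm", "ttest-rf", "ttest-svm")


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end settings; defaults mirror the canonical study design."""

    descriptor: DescriptorConfig = field(default_factory=DescriptorConfig)
    redundancy_threshold: float | None = 0.9  # None skips the greedy clustering
    train_fraction: float = 0.8
    corr_cutoff: float = 0.9
    ttest_alpha: float = 0.05
    mdg_rule: str = "above-mean"
    mdg_top_k: int | None = None
    mdg_trees: int = 500
    branches: tuple[str, ...] = DEFAULT_BRANCHES
    rfe_sizes: tuple[int, ...] | None = None  # None -> automatic grid
    rfe_trees: int = 100
    cv_folds: int = 10
    cv_repeats: int = 5
    svm_grid: SvmGrid = field(default_factory=SvmGrid)
    rf_grid: RfGrid = field(default_factory=RfGrid)

    def reduced(self, cv_folds: int = 5, cv_repeats: int = 2) -> "PipelineConfig":
        """A cheaper variant for quick runs: lighter repeated CV."""
        return replace(self, cv_folds=cv_folds, cv_repeats=cv_repeats)


@dataclass
class BranchResult:
    name: str
    selection: sel.SelectionReport
    classifier: TrainedClassifier
    evaluation: MetricsReport
    test_probabilities: pd.DataFrame  # id-indexed: probability, label, true
    test_auc: float


class BacteriocinModel:
    """Bacteriocin-vs-non-bacteriocin classifier pipeline bound to a dataset.

    Parameters
    ----------
    dataset : LabeledDataset
        Validated records labeled +1 (bacteriocin) / -1 (non-bacteriocin).
    config : PipelineConfig, optional

    Examples
    --------
    >>> from bactipred import BacteriocinModel, SyntheticSpec, generate
    >>> data = generate(SyntheticSpec(n_per_class=60, seed=7))
    >>> res = BacteriocinModel(data).fit(seed=7)     # doctest: +SKIP
    >>> print(res.summary())                          # doctest: +SKIP
    """

    def __init__(self, dataset: LabeledDataset, config: PipelineConfig | None = None):
        if dataset.n_pos == 0 or dataset.n_neg == 0:
            raise ValueError("dataset must contain both classes")
        self.dataset = dataset
        self.config = config or PipelineConfig()

    @classmethod
    def from_fasta(cls, positives, negatives, config: PipelineConfig | None = None,
                   policy: str = "reject") -> "BacteriocinModel":
        pos = read_fasta(positives, label=POSITIVE, policy=policy)
        neg = read_fasta(negatives, label=NEGATIVE, policy=policy)
        return cls(pos.merged_with(neg), config)

    @classmethod
    def from_split_fasta(cls, train_pos, train_neg, test_pos, test_neg,
                         config: PipelineConfig | None = None) -> "BacteriocinModel":
        """Build from pre-made train/test FASTA files (authoritative splits)."""
        model = cls.from_fasta(train_pos, train_neg, config)
        test = read_fasta(test_pos, label=POSITIVE).merged_with(
            read_fasta(test_neg, label=NEGATIVE)
        )
        model._fixed_test = test
        return model

    _fixed_test: LabeledDataset | None = None

    # ------------------------------------------------------------------
    def fit(self, seed: int = 0) -> "BacteriocinResults":
        cfg = self.config
        data = self.dataset
        if cfg.redundancy_threshold is not None:
            data = reduce_redundancy(data, cfg.redundancy_threshold)
        if data.n_pos != data.n_neg:
            data = balance_by_subsampling(data, seed=seed)
        if self._fixed_test is not None:
            train, test = data, self._fixed_test
        else:
            train, test = stratified_split(data, cfg.train_fraction, seed=seed)

        X_train = build_feature_matrix(train, cfg.descriptor)
        y_train = labels_vector(train)
        X_test = build_feature_matrix(test, cfg.descriptor)
        y_test = labels_vector(test)

        # stage 1: correlation filter, shared by all branches
        corr = sel.pearson_filter(X_train, cfg.corr_cutoff)
        X_corr = X_train[corr.retained]

        ttest_res = mdg_res = None
        reduced_sets: dict[str, list[str]] = {}
        if any(b.startswith("ttest") for b in cfg.branches):
            ttest_res = sel.ttest_filter(X_corr, y_train, cfg.ttest_alpha)
            reduced_sets["ttest"] = ttest_res.retained
        if any(b.startswith("mdg") for b in cfg.branches):
            mdg_res = sel.mdg_select(
                X_corr, y_train, n_trees=cfg.mdg_trees, rule=cfg.mdg_rule,
                top_k=cfg.mdg_top_k, seed=seed,
            )
            reduced_sets["mdg"] = mdg_res.selected

        branches: dict[str, BranchResult] = {}
        for branch in cfg.branches:
            set_name, est = branch.rsplit("-", 1)
            features = reduced_sets[set_name]
            if len(features) < 2:
                raise ValueError(
                    f"branch {branch}: only {len(features)} feature(s) survived "
                    f"the {set_name} filter"
                )
            sizes = list(cfg.rfe_sizes) if cfg.rfe_sizes else None
            if sizes is not None:
                sizes = [s for s in sizes if s <= len(features)] or [len(features)]
            rfe_res = sel.rfe(
                X_train[features], y_train, estimator=est, sizes=sizes,
                cv_folds=cfg.cv_folds, cv_repeats=cfg.cv_repeats,
                seed=seed, n_trees=cfg.rfe_trees,
            )
            report = sel.SelectionReport(
                correlation=corr, branch=set_name,
                ttest=ttest_res if set_name == "ttest" else None,
                mdg=mdg_res if set_name == "mdg" else None,
                rfe=rfe_res, selected=rfe_res.selected,
            )
            grid = cfg.svm_grid if est == "svm" else cfg.rf_grid
            clf = tune_and_train(
                X_train[rfe_res.selected], y_train, algorithm=est, grid=grid,
                cv_folds=cfg.cv_folds, cv_repeats=cfg.cv_repeats, seed=seed,
            )
            pred = clf.predict_proba(X_test[rfe_res.selected])
            pred["true"] = y_test
            cm = confusion(pred["label"].to_numpy(), y_test)
            report_metrics = metrics(cm, ci_level=0.95)
            auc = sel.roc_auc(pred["probability"].to_numpy(), y_test)
            branches[branch] = BranchResult(
                branch, report, clf, report_metrics, pred, auc
            )
        return BacteriocinResults(self, branches, train, test, seed)


class BacteriocinResults:
    """Fitted-pipeline results: per-branch classifiers, selection reports,
    held-out metrics, and convenience accessors for the best branch."""

    def __init__(self, model: BacteriocinModel, branches: dict[str, BranchResult],
                 train: LabeledDataset, test: LabeledDataset, seed: int):
        self.model = model
        self.branches = branches
        self.train_set = train
        self.test_set = test
        self.seed = seed

    @property
    def best_branch(self) -> BranchResult:
        """Branch with the highest held-out MCC (ties: accuracy, then name)."""
        return max(
            self.branches.values(),
            key=lambda b: (b.evaluation.mcc, b.evaluation.accuracy, b.name),
        )

    @property
    def classifier(self) -> TrainedClassifier:
        return self.best_branch.classifier

    @property
    def evaluation(self) -> MetricsReport:
        return self.best_branch.evaluation

    @property
    def selection(self) -> sel.SelectionReport:
        return self.best_branch.selection

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for name, b in sorted(self.branches.items()):
            e = b.evaluation
            rows.append({
                "branch": name,
                "n_features": len(b.selection.selected),
                "cv_auc": b.classifier.cv_auc,
                "test_auc": b.test_auc,
                "accuracy": e.accuracy,
                "mcc": e.mcc,
                "recall": e.recall,
                "precision": e.precision,
                "f1": e.f1,
                "ci_lower": e.ci[0],
                "ci_upper": e.ci[1],
            })
        return pd.DataFrame(rows).set_index("branch")

    def identity_baseline(self, thresholds=tuple(range(20, 100, 10))) -> pd.DataFrame:
        """Percent-identity best-hit sweep: positive test vs positive train
        sequences and negative test vs negative train, per threshold."""
        frames = []
        for lab, tag in ((POSITIVE, "positive"), (NEGATIVE, "negative")):
            q = LabeledDataset(self.test_set.subset(lab))
            s = LabeledDataset(self.train_set.subset(lab))
            df = identity_baseline_sweep(q, s, thresholds)
            df["class"] = tag
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        best = self.best_branch
        e = best.evaluation
        lines = [
            "Bacteriocin classification pipeline",
            "=" * 68,
            f"training sequences: {len(self.train_set)} "
            f"({self.train_set.n_pos} pos / {self.train_set.n_neg} neg)",
            f"test sequences:     {len(self.test_set)} "
            f"({self.test_set.n_pos} pos / {self.test_set.n_neg} neg)",
            f"seed: {self.seed}",
            "",
            "per-branch held-out performance",
            "-" * 68,
            self.metrics_frame().round(4).to_string(),
            "",
            f"best branch: {best.name} "
            f"({best.classifier.algorithm}, {best.classifier.params})",
            f"  selected features: {len(best.selection.selected)}",
            f"  stage counts: {best.selection.stage_counts()}",
            f"  accuracy {e.accuracy:.4f}  (95% CI {e.ci[0]:.4f}-{e.ci[1]:.4f})",
            f"  MCC {e.mcc:.4f}  recall {e.recall:.4f}  "
            f"precision {e.precision:.4f}  F1 {e.f1:.4f}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        b = self.best_branch
        return (f"<BacteriocinResults: {len(self.branches)} branch(es), "
                f"best={b.name} acc={b.evaluation.accuracy:.3f}>")
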