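"""Binary-classification evaluation and the sequence-identity baseline.

Metrics: accuracy, Matthews correlation coefficient, recall, precision and
F1 from the confusion counts; an exact (Clopper-Pearson) binomial confidence
interval on the accuracy; a paired t-test for comparing two models'
probability scores on the same test items; and a percent-identity sweep
that emulates a BLASTP-style best-hit baseline with a local BLOSUM62
aligner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .sequence_io import LabeledDataset


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def correct(self) -> int:
        return self.tp + self.tn


def confusion(predicted, true) -> ConfusionMatrix:
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.shape != true.shape:
        raise ValueError("predicted and true label vectors differ in length")
    for v in np.unique(np.concatenate([predicted, true])):
        if v not in (1, -1):
            raise ValueError(f"labels must be +1/-1, got {v}")
    return ConfusionMatrix(
        tp=int(((predicted == 1) & (true == 1)).sum()),
        tn=int(((predicted == -1) & (true == -1)).sum()),
        fp=int(((predicted == 1) & (true == -1)).sum()),
        fn=int(((predicted == -1) & (true == 1)).sum()),
    )


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    mcc: float
    recall: float
    precision: float
    f1: float
    ci: tuple[float, float] | None = None
    confusion: ConfusionMatrix | None = None

    def as_dict(self) -> dict:
        out = {
            "accuracy": self.accuracy,
            "mcc": self.mcc,
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
        }
        if self.ci is not None:
            out["ci_lower"], out["ci_upper"] = self.ci
        if self.confusion is not None:
            cm = self.confusion
            out.update(tp=cm.tp, tn=cm.tn, fp=cm.fp, fn=cm.fn)
        return out


def metrics(cm: ConfusionMatrix, ci_level: float | None = None) -> MetricsReport:
    """Accuracy, MCC, recall, precision, F1 from confusion counts.

    Degenerate denominators follow fixed conventions: precision and recall
    are 0 when undefined, MCC is 0 when any factor under the root is 0, F1
    is 0 when precision + recall = 0.
    """
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    acc = (tp + tn) / cm.total
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom2) if denom2 > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    ci = accuracy_ci(cm.correct, cm.total, ci_level) if ci_level else None
    return MetricsReport(acc, float(mcc), recall, precision, f1, ci, cm)


def accuracy_ci(correct: int, total: int, level: float = 0.95) -> tuple[float, float]:
    """Exact Clopper-Pearson binomial confidence interval for correct/total."""
    if total < 1 or not (0 <= correct <= total):
        raise ValueError("need 0 <= correct <= total and total >= 1")
    lo, hi = proportion_confint(correct, total, alpha=1.0 - level, method="beta")
    return float(lo), float(hi)


def paired_probability_ttest(probs_a, probs_b) -> tuple[float, float]:
    """Paired t-test on probability scores of two models over the same items.

    Returns (mean of a-b, two-sided p).  Zero-variance differences have no
    sampling noise: p = 1 when the mean difference is exactly 0, else p = 0.
    """
    a = np.asarray(probs_a, dtype=float)
    b = np.asarray(probs_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    d = a - b
    mean_diff = float(d.mean())
    if np.allclose(d.std(ddof=1), 0.0):
        return mean_diff, 1.0 if np.isclose(mean_diff, 0.0) else 0.0
    t = stats.ttest_rel(a, b)
    return mean_diff, float(t.pvalue)


def _blosum_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def best_hit_identity(query: str, subjects: list[str]) -> float:
    """Best percent identity of a query over subject sequences: local
    BLOSUM62 alignment (gap open 11 / extend 1), identity = matches over
    alignment columns x 100."""
    aligner = _blosum_aligner()
    best = 0.0
    for subj in subjects:
        aln = aligner.align(query, subj)
        if len(aln) == 0:  # pragma: no cover - BLOSUM62 always aligns something
            continue
        counts = aln[0].counts()
        cols = counts.identities + counts.mismatches + counts.gaps
        if cols:
            best = max(best, 100.0 * counts.identities / cols)
    return best


def identity_baseline_sweep(
    queries: LabeledDataset,
    subjects: LabeledDataset,
    thresholds=tuple(range(20, 100, 10)),
) -> pd.DataFrame:
    """Per threshold, the number of queries whose best percent identity to
    any subject is >= the threshold.  Counts are non-increasing in the
    threshold; this is the sequence-matching detector the classifier is
    compared against."""
    if len(subjects) == 0:
        raise ValueError("subject set is empty")
    if len(queries) == 0:
        raise ValueError("query set is empty")
    subject_seqs = [r.sequence for r in subjects]
    best = np.array([best_hit_identity(q.sequence, subject_seqs) for q in queries])
    rows = [(float(t), int((best >= t).sum())) for t in thresholds]
    return pd.DataFrame(rows, columns=["threshold", "count"])
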