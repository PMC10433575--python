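"""Classifier training: grid-tuned SVM-RBF and random forest.

Features are z-scored with constants taken from the training rows only.
The SVM tunes only the cost C over {4, 8, 16, 32, 64, 128}; the RBF width is
fixed beforehand by the median-distance heuristic on the standardized
training data.  The forest tunes n_estimators over {400, 500} and the
per-split candidate count (mtry) over {5, 6}.  Grid points are scored by
mean repeated stratified k-fold cross-validated AUC; ties break to the
smaller parameter so runs are reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold, cross_val_score
from sklearn.svm import SVC

_BUNDLE_VERSION = 1

SVM_COST_GRID = (4.0, 8.0, 16.0, 32.0, 64.0, 128.0)
RF_NTREE_GRID = (400, 500)
RF_MTRY_GRID = (5, 6)


@dataclass(frozen=True)
class SvmGrid:
    costs: tuple[float, ...] = SVM_COST_GRID

    def __post_init__(self):
        if not self.costs or any(c <= 0 for c in self.costs):
            raise ValueError("cost grid must be non-empty and positive")


@dataclass(frozen=True)
class RfGrid:
    ntree: tuple[int, ...] = RF_NTREE_GRID
    mtry: tuple[int, ...] = RF_MTRY_GRID

    def __post_init__(self):
        if not self.ntree or not self.mtry:
            raise ValueError("grids must be non-empty")
        if any(v < 1 for v in self.ntree) or any(v < 1 for v in self.mtry):
            raise ValueError("grid values must be positive integers")


def median_heuristic_gamma(X: np.ndarray) -> float:
    """RBF gamma = 1 / median squared pairwise Euclidean distance (nonzero
    distances only), computed on standardized training rows."""
    d2 = pdist(X, metric="sqeuclidean")
    d2 = d2[d2 > 0]
    if len(d2) == 0:
        return 1.0
    return float(1.0 / np.median(d2))


@dataclass
class TrainedClassifier:
    """Fitted model bundle: algorithm, hyperparameters, frozen feature list
    and the training-set standardization constants."""

    algorithm: str  # "svm" | "rf"
    params: dict
    feature_names: list[str]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    model: object
    cv_auc: float
    seed: int
    metadata: dict = field(default_factory=dict)

    def _check_and_transform(self, matrix: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in matrix.columns]
        if missing:
            raise ValueError(
                f"input matrix is missing {len(missing)} model feature(s): "
                f"{', '.join(missing[:5])}{' ...' if len(missing) > 5 else ''}"
            )
        X = matrix[self.feature_names].to_numpy(dtype=float)
        if not np.isfinite(X).all():
            raise ValueError("NaN or infinite feature values")
        return (X - self.scaler_mean) / self.scaler_scale

    def predict_proba(self, matrix: pd.DataFrame) -> pd.DataFrame:
        """Per row: P(bacteriocin) and the implied label (+1 iff P >= 0.5)."""
        X = self._check_and_transform(matrix)
        pos_col = int(np.where(self.model.classes_ == 1)[0][0])
        proba = self.model.predict_proba(X)[:, pos_col]
        labels = np.where(proba >= 0.5, 1, -1)
        return pd.DataFrame(
            {"probability": proba, "label": labels}, index=matrix.index
        )


def _standardize_train(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0.0] = 1.0  # constant feature: leave centred at 0
    return (X - mean) / scale, mean, scale


def tune_and_train(
    matrix: pd.DataFrame,
    labels,
    algorithm: str = "svm",
    grid: SvmGrid | RfGrid | None = None,
    cv_folds: int = 10,
    cv_repeats: int = 5,
    seed: int = 0,
) -> TrainedClassifier:
    """Grid search by mean CV-AUC, then refit the winner on all training rows.

    SVM probabilities come from Platt scaling (internal 5-fold CV); RF
    probabilities are the fraction of trees voting for the positive class.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError("training needs exactly two classes")
    if cv_folds > counts.min():
        raise ValueError(
            f"cv_folds={cv_folds} exceeds smallest class count {counts.min()}"
        )
    X_raw = matrix.to_numpy(dtype=float)
    if not np.isfinite(X_raw).all():
        raise ValueError("NaN or infinite feature values in training matrix")
    X, mean, scale = _standardize_train(X_raw)
    cv = RepeatedStratifiedKFold(n_splits=cv_folds, n_repeats=cv_repeats, random_state=seed)

    if algorithm == "svm":
        grid = grid or SvmGrid()
        gamma = median_heuristic_gamma(X)
        # grid search scores the raw decision function; the winner is then
        # wrapped in Platt scaling (sigmoid calibration, internal 5-fold CV)
        # so predict_proba is available.
        calib_cv = min(5, int(counts.min()))
        candidates = [
            (
                {"C": c, "gamma": gamma},
                SVC(kernel="rbf", C=c, gamma=gamma, random_state=seed),
                CalibratedClassifierCV(
                    SVC(kernel="rbf", C=c, gamma=gamma, random_state=seed),
                    method="sigmoid", cv=calib_cv, ensemble=False,
                ),
            )
            for c in sorted(grid.costs)
        ]
    elif algorithm == "rf":
        grid = grid or RfGrid()
        max_mtry = matrix.shape[1]
        candidates = []
        for nt in sorted(grid.ntree):
            for mt in sorted(grid.mtry):
                forest = RandomForestClassifier(
                    n_estimators=nt, max_features=min(mt, max_mtry),
                    random_state=seed, n_jobs=1,
                )
                candidates.append(({"ntree": nt, "mtry": mt}, forest, forest))
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")

    best_params, best_model, best_auc = None, None, -np.inf
    for params, scoring_est, final_est in candidates:
        aucs = cross_val_score(scoring_est, X, labels, cv=cv, scoring="roc_auc", n_jobs=1)
        score = float(aucs.mean())
        if score > best_auc:  # strict: earlier (smaller) grid point wins ties
            best_params, best_model, best_auc = params, final_est, score
    best_model.fit(X, labels)
    return TrainedClassifier(
        algorithm=algorithm,
        params=best_params,
        feature_names=list(matrix.columns),
        scaler_mean=mean,
        scaler_scale=scale,
        model=best_model,
        cv_auc=best_auc,
        seed=seed,
        metadata={"cv_folds": cv_folds, "cv_repeats": cv_repeats,
                  "n_train": len(labels)},
    )


def predict_proba(model: TrainedClassifier, matrix: pd.DataFrame) -> pd.DataFrame:
    return model.predict_proba(matrix)


def save_model(model: TrainedClassifier, path) -> None:
    """Persist the bundle plus a human-readable sidecar JSON (<path>.json)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    joblib.dump({"version": _BUNDLE_VERSION, "bundle": model}, path)
    sidecar = {
        "version": _BUNDLE_VERSION,
        "algorithm": model.algorithm,
        "params": model.params,
        "n_features": len(model.feature_names),
        "feature_names": model.feature_names,
        "cv_auc": model.cv_auc,
        "seed": model.seed,
        "metadata": model.metadata,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path) -> TrainedClassifier:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model file not found: {path}")
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ValueError(f"corrupted or unreadable model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("version") != _BUNDLE_VERSION:
        raise ValueError(
            f"model file {path} has unsupported version "
            f"{payload.get('version') if isinstance(payload, dict) else '?'}"
        )
    return payload["bundle"]
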