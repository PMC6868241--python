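"""Gradient-boosted decision-tree classifier: tuning, training, prediction.

The classifier separates pathogenic from control positions on the feature
matrix. Hyperparameters are tuned by randomized search — by default 1000
candidate configurations drawn uniformly from the search space, each scored
by mean ROC-AUC over stratified 5-fold cross-validation — and the best
configuration is refit on the full training set. The published tuned
configuration (32 estimators, depth 31, learning rate 0.31, minimum child
weight 6.17) is the default when no search is run.

Missing feature values are routed natively by the trees; predictions are
probabilities in [0, 1] (0 = non-essential, 1 = putative essential).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

__all__ = [
    "ModelConfig",
    "TrainedEnsemble",
    "FeatureImportanceReport",
    "random_search",
    "train",
    "predict",
    "feature_importance",
    "split_matrix",
]

#: Search-space bounds (uniform; learning_rate log-uniform).
DEFAULT_SEARCH_SPACE: dict[str, tuple[float, float]] = {
    "n_estimators": (10, 500),
    "max_depth": (2, 40),
    "learning_rate": (0.01, 0.5),
    "min_child_weight": (0.5, 20.0),
}


@dataclass
class ModelConfig:
    """Hyperparameters plus the randomized-search settings used to find them."""

    n_estimators: int = 32
    max_depth: int = 31
    learning_rate: float = 0.31
    min_child_weight: float = 6.17
    search_space: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SEARCH_SPACE)
    )
    n_candidates: int = 1000
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_estimators, self.max_depth) <= 0:
            raise ValueError("tree counts and depth must be positive")
        if self.learning_rate <= 0 or self.min_child_weight <= 0:
            raise ValueError("learning_rate and min_child_weight must be positive")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")

    def estimator(self) -> XGBClassifier:
        return XGBClassifier(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            min_child_weight=self.min_child_weight,
            objective="binary:logistic",
            tree_method="hist",
            random_state=self.seed,
            n_jobs=1,
            eval_metric="logloss",
        )


@dataclass
class TrainedEnsemble:
    """A fitted ensemble with its feature-name order frozen at fit time."""

    model: XGBClassifier
    feature_names: list[str]
    config: ModelConfig


@dataclass
class FeatureImportanceReport:
    importances: pd.Series  # indexed by feature name, non-negative
    n_contributing: int


def split_matrix(matrix: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Separate the feature block from the binary label column.

    Labels: 'pathogenic' -> 1, anything else -> 0.
    """
    if "label" not in matrix.columns:
        raise ValueError("matrix has no label column")
    y = (matrix["label"].to_numpy() == "pathogenic").astype(int)
    X = matrix.drop(columns=["label"])
    return X, y


def _cv_auc(X: pd.DataFrame, y: np.ndarray, config: ModelConfig) -> float:
    """Mean ROC-AUC over stratified folds for one hyperparameter set."""
    counts = np.bincount(y, minlength=2)
    if counts.min() < config.folds:
        raise ValueError(
            f"cannot stratify {config.folds} folds: minority class has "
            f"{counts.min()} rows"
        )
    skf = StratifiedKFold(
        n_splits=config.folds, shuffle=True, random_state=config.seed
    )
    aucs = []
    for tr, te in skf.split(X, y):
        est = config.estimator()
        est.fit(X.iloc[tr], y[tr])
        aucs.append(roc_auc_score(y[te], est.predict_proba(X.iloc[te])[:, 1]))
    return float(np.mean(aucs))


def _draw_candidate(rng: np.random.Generator, space: dict) -> dict:
    lo, hi = space["n_estimators"]
    n_est = int(rng.integers(int(lo), int(hi) + 1))
    lo, hi = space["max_depth"]
    depth = int(rng.integers(int(lo), int(hi) + 1))
    lo, hi = space["learning_rate"]
    lr = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    lo, hi = space["min_child_weight"]
    mcw = float(rng.uniform(lo, hi))
    return {
        "n_estimators": n_est,
        "max_depth": depth,
        "learning_rate": lr,
        "min_child_weight": mcw,
    }


def random_search(
    matrix: pd.DataFrame,
    config: ModelConfig,
    return_trials: bool = False,
) -> ModelConfig | tuple[ModelConfig, pd.DataFrame]:
    """Randomized hyperparameter search scored by cross-validated ROC-AUC.

    Draws ``config.n_candidates`` hyperparameter sets uniformly from
    ``config.search_space`` (learning rate on a log scale), evaluates each
    by mean ROC-AUC over ``config.folds`` stratified folds, and returns the
    configuration with the highest mean AUC. With ``return_trials`` the
    full per-candidate table is returned as well.
    """
    X, y = split_matrix(matrix)
    rng = np.random.default_rng(config.seed)
    rows = []
    best: tuple[float, dict] | None = None
    for i in range(config.n_candidates):
        params = _draw_candidate(rng, config.search_space)
        cand = replace(config, **params)
        auc = _cv_auc(X, y, cand)
        rows.append({**params, "mean_cv_auc": auc})
        if best is None or auc > best[0]:
            best = (auc, params)
    assert best is not None
    tuned = replace(config, **best[1])
    if return_trials:
        return tuned, pd.DataFrame(rows)
    return tuned


def train(matrix: pd.DataFrame, config: ModelConfig) -> TrainedEnsemble:
    """Fit the ensemble on the full matrix with the given hyperparameters."""
    X, y = split_matrix(matrix)
    if len(X) == 0:
        raise ValueError("empty feature matrix")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    est = config.estimator()
    est.fit(X, y)
    return TrainedEnsemble(model=est, feature_names=list(X.columns), config=config)


def predict(ensemble: TrainedEnsemble, matrix: pd.DataFrame) -> np.ndarray:
    """Per-row scores in [0, 1]; columns are aligned to the model by name."""
    X = matrix.drop(columns=["label"], errors="ignore")
    have = set(X.columns)
    want = set(ensemble.feature_names)
    if have != want:
        raise ValueError(
            "feature mismatch; missing="
            f"{sorted(want - have)} unexpected={sorted(have - want)}"
        )
    X = X[ensemble.feature_names]
    return ensemble.model.predict_proba(X)[:, 1]


def feature_importance(ensemble: TrainedEnsemble) -> FeatureImportanceReport:
    """Per-feature importance (gain-based, 0 for unused features)."""
    imp = pd.Series(
        np.asarray(ensemble.model.feature_importances_, dtype=float),
        index=ensemble.feature_names,
    )
    return FeatureImportanceReport(
        importances=imp, n_contributing=int((imp > 0).sum())
    )
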