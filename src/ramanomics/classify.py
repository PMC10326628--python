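"""Sample-grouped splitting and classifier training on PCA scores.

All partitioning is at the biological-sample level: the five replicate
spectra of a sample never straddle the train/test boundary or a
cross-validation fold, because the outcome label is a property of the
sample and replicate leakage would inflate accuracy.  Four classifier
families are supported — a 1D convolutional network, support vector
machine, random forest and gradient-boosted trees — each tuned by
exhaustive grid search with group-aware k-fold cross-validation on the
training partition and refit on the full training data.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GroupKFold
from sklearn.svm import SVC
from xgboost import XGBClassifier

from ramanomics.cnn import Conv1DClassifier

logger = logging.getLogger(__name__)

#: Class order fixes the integer encoding and probability column order.
CLASS_ORDER = ("pregnancy", "non_pregnancy")

ALGORITHMS = ("cnn1d", "svm", "rf", "xgboost")

#: Default hyperparameter grids, one per algorithm family.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "cnn1d": {"n_conv_layers": [1, 2], "n_kernels": [8, 16, 32]},
    "svm": {"kernel": ["rbf", "linear"], "C": [0.1, 1.0, 10.0],
            "gamma": ["scale", 0.01, 0.001]},
    "rf": {"n_estimators": [100, 300], "max_depth": [None, 10, 20],
           "min_samples_split": [2, 5]},
    "xgboost": {"n_estimators": [100, 300], "max_depth": [3, 6],
                "learning_rate": [0.1, 0.3], "subsample": [0.8, 1.0]},
}


class StratificationError(ValueError):
    """A class label is absent or too sparse to split."""


class SpecificationError(ValueError):
    """Invalid classifier specification (empty grid, bad folds, ...)."""


def encode_labels(labels) -> np.ndarray:
    """Map class names onto {0: pregnancy, 1: non_pregnancy}."""
    lut = {name: i for i, name in enumerate(CLASS_ORDER)}
    try:
        return np.array([lut[l] for l in labels], dtype=int)
    except KeyError as exc:
        raise ValueError(f"unknown label {exc.args[0]!r}; expected {CLASS_ORDER}") from exc


def decode_labels(codes: np.ndarray) -> np.ndarray:
    return np.array([CLASS_ORDER[c] for c in np.asarray(codes, dtype=int)], dtype=object)


@dataclass(frozen=True)
class SplitPlan:
    train_samples: tuple[str, ...]
    test_samples: tuple[str, ...]
    seed: int

    def __post_init__(self):
        overlap = set(self.train_samples) & set(self.test_samples)
        if overlap:
            raise ValueError(f"samples in both partitions: {sorted(overlap)}")

    def mask(self, sample_ids) -> np.ndarray:
        """Boolean train-membership mask over an array of sample ids."""
        train = set(self.train_samples)
        return np.array([sid in train for sid in sample_ids], dtype=bool)


def make_split(manifest: pd.DataFrame, ratio: float = 0.8, seed: int = 0) -> SplitPlan:
    """Stratified sample-level train/test split.

    Samples (never individual spectra) are assigned to one partition,
    stratified by outcome so each partition's label mix stays within one
    sample of the configured balance.  Deterministic for a given seed.
    """
    if not 0.0 < ratio < 1.0:
        raise SpecificationError("ratio must be in (0, 1)")
    per_sample = manifest.drop_duplicates("sample_id")[["sample_id", "label"]]
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for label in CLASS_ORDER:
        ids = per_sample.loc[per_sample["label"] == label, "sample_id"].tolist()
        if len(ids) < 2:
            raise StratificationError(
                f"label {label!r} has {len(ids)} sample(s); need >= 2 to split")
        ids = sorted(ids)
        rng.shuffle(ids)
        n_train = int(round(ratio * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        train.extend(ids[:n_train])
        test.extend(ids[n_train:])
    return SplitPlan(tuple(sorted(train)), tuple(sorted(test)), seed)


@dataclass
class ClassifierSpec:
    algorithm: str
    grid: dict[str, list] | None = None   # None -> DEFAULT_GRIDS[algorithm]
    cv_folds: int = 5
    seed: int = 0
    fixed_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise SpecificationError(f"algorithm must be one of {ALGORITHMS}")
        if self.grid is None:
            self.grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.algorithm].items()}
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise SpecificationError("hyperparameter grid must be non-empty")
        if self.cv_folds < 2:
            raise SpecificationError("cv_folds must be >= 2")


def _build_estimator(algorithm: str, params: dict, seed: int):
    if algorithm == "svm":
        return SVC(probability=True, random_state=seed, **params)
    if algorithm == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if algorithm == "xgboost":
        return XGBClassifier(random_state=seed, n_jobs=1, tree_method="hist",
                             eval_metric="logloss", **params)
    if algorithm == "cnn1d":
        return Conv1DClassifier(seed=seed, **params)
    raise SpecificationError(f"unknown algorithm {algorithm!r}")


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    estimator: object
    best_params: dict
    cv_accuracy: float
    classes: tuple[str, ...] = CLASS_ORDER


def group_folds(y: np.ndarray, groups: np.ndarray, cv_folds: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Group-aware k-fold indices: a sample's replicates share a fold.

    Raises if a training fold would be single-class.
    """
    groups = np.asarray(groups)
    n_groups = len(np.unique(groups))
    folds = min(cv_folds, n_groups)
    if folds < 2:
        raise SpecificationError("need at least 2 distinct sample groups for CV")
    splitter = GroupKFold(n_splits=folds)
    fold_indices = list(splitter.split(np.zeros((len(groups), 1)), y, groups))
    for tr, _ in fold_indices:
        if len(np.unique(np.asarray(y)[tr])) < 2:
            raise SpecificationError("degenerate CV fold with a single class")
    return fold_indices


def grid_points(grid: dict[str, list]):
    """Grid points in listed order (first-listed wins CV ties)."""
    keys = list(grid)
    for combo in itertools.product(*(grid[k] for k in keys)):
        yield dict(zip(keys, combo))


def grid_search_cv(spec: ClassifierSpec, scores: np.ndarray, labels,
                   groups) -> TrainedModel:
    """Exhaustive grid search with group-aware k-fold cross-validation.

    Folds are split by sample id so replicate spectra of one sample stay
    in one fold.  The best grid point by mean CV accuracy (ties broken
    by listing order) is refit on all training data.
    """
    X = np.asarray(scores, dtype=float)
    y = encode_labels(labels)
    groups = np.asarray(groups)
    fold_indices = group_folds(y, groups, spec.cv_folds)

    best_acc, best_params = -1.0, None
    for params in grid_points(spec.grid):
        accs = []
        for tr, va in fold_indices:
            est = _build_estimator(spec.algorithm, {**spec.fixed_params, **params}, spec.seed)
            if isinstance(est, Conv1DClassifier):
                est.fit(X[tr], y[tr], X_val=X[va], y_val=y[va])
            else:
                est.fit(X[tr], y[tr])
            accs.append(float(np.mean(est.predict(X[va]) == y[va])))
        acc = float(np.mean(accs))
        logger.debug("%s %s: CV accuracy %.4f", spec.algorithm, params, acc)
        if acc > best_acc:  # strict: ties keep the first-listed point
            best_acc, best_params = acc, params
    final = _build_estimator(spec.algorithm, {**spec.fixed_params, **best_params}, spec.seed)
    final.fit(X, y)
    return TrainedModel(spec=spec, estimator=final, best_params=best_params,
                        cv_accuracy=best_acc)


def predict(model: TrainedModel, scores: np.ndarray) -> pd.DataFrame:
    """Per-spectrum class probabilities and hard labels.

    Probabilities are returned in :data:`CLASS_ORDER` column order; the
    hard label is the argmax, with exact ties resolved to
    ``non_pregnancy`` (the class whose mis-selection is the cheaper
    clinical error).
    """
    X = np.asarray(scores, dtype=float)
    proba = np.asarray(model.estimator.predict_proba(X), dtype=float)
    if proba.shape[1] != 2:
        raise ValueError("expected binary class probabilities")
    hard = np.where(proba[:, 1] >= proba[:, 0], CLASS_ORDER[1], CLASS_ORDER[0])
    return pd.DataFrame({
        "p_pregnancy": proba[:, 0],
        "p_non_pregnancy": proba[:, 1],
        "predicted": hard,
    })


def aggregate_by_sample(predictions: pd.DataFrame, sample_ids) -> pd.DataFrame:
    """Majority vote over a sample's replicate predictions (ties -> non_pregnancy)."""
    df = predictions.copy()
    df["sample_id"] = np.asarray(sample_ids)
    rows = []
    for sid, sub in df.groupby("sample_id", sort=True):
        n_non = int((sub["predicted"] == "non_pregnancy").sum())
        n_preg = len(sub) - n_non
        rows.append({"sample_id": sid,
                     "predicted": "non_pregnancy" if n_non >= n_preg else "pregnancy",
                     "n_replicates": len(sub)})
    return pd.DataFrame(rows)
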