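"""Dataset partitioning, grid-search CV and model training.

The protocol: a stratified 9:1 train/test split, then 5-fold stratified
cross-validation over the training portion for hyperparameter selection,
with mean validation accuracy as the objective. Random forest, SVM and kNN
are searched exhaustively over fixed discrete grids (24, 16 and 20
configurations respectively); the fully connected network is tuned by a
seeded random search over its bounded space and refit on the full training
split. Ties in grid search go to the earlier-listed configuration.

The test rows are never touched by selection or search — only by the final
evaluation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .fcnn import FCNNClassifier
from .featurize import DescriptorBlock, FingerprintBlock

ALGORITHMS = ("rf", "svm", "knn", "fcnn")
VIEWS = ("maccs", "morgan", "descriptors", "multiview")

#: Discrete hyperparameter grids for the three ML classifiers.
DEFAULT_GRIDS: Dict[str, Dict[str, list]] = {
    "rf": {
        "n_estimators": [50, 100, 200],
        "max_depth": [None, 5, 10, 20],
        "min_samples_split": [2, 5],
    },
    "svm": {
        "C": [0.1, 1, 10, 100],
        "kernel": ["linear", "poly", "rbf", "sigmoid"],
    },
    "knn": {
        "n_neighbors": [3, 5, 7, 9, 11],
        "weights": ["uniform", "distance"],
        "metric": ["euclidean", "manhattan"],
    },
}


@dataclass
class SplitPlan:
    train_idx: np.ndarray
    test_idx: np.ndarray
    folds: List[Tuple[np.ndarray, np.ndarray]]   # global indices within train
    seed: int


@dataclass
class FcnnSpace:
    """Bounded stochastic search space for the network."""

    lr_low: float = 1e-5
    lr_high: float = 1e-2
    batch_sizes: tuple = (32, 64)
    layer1_sizes: tuple = (256, 512, 1024)
    layer2_sizes: tuple = (64, 128, 256)
    dropout_rates: tuple = (0.1, 0.2, 0.3, 0.4, 0.5)

    def sample(self, rng: np.random.Generator) -> dict:
        return {
            "learning_rate": float(np.exp(rng.uniform(np.log(self.lr_low),
                                                      np.log(self.lr_high)))),
            "batch_size": int(rng.choice(self.batch_sizes)),
            "hidden1": int(rng.choice(self.layer1_sizes)),
            "hidden2": int(rng.choice(self.layer2_sizes)),
            "dropout1": float(rng.choice(self.dropout_rates)),
            "dropout2": float(rng.choice(self.dropout_rates)),
        }

    def contains(self, cfg: dict) -> bool:
        return (self.lr_low <= cfg["learning_rate"] <= self.lr_high
                and cfg["batch_size"] in self.batch_sizes
                and cfg["hidden1"] in self.layer1_sizes
                and cfg["hidden2"] in self.layer2_sizes
                and cfg["dropout1"] in self.dropout_rates
                and cfg["dropout2"] in self.dropout_rates)


@dataclass
class MultiViewMatrix:
    """Column-stacked [morgan | maccs | selected descriptors] matrix."""

    values: np.ndarray
    provenance: np.ndarray        # per-column view tag
    names: List[str]

    def __post_init__(self) -> None:
        if len(self.names) != self.values.shape[1] or \
                len(self.provenance) != self.values.shape[1]:
            raise ValueError("provenance/names must match column count")


def build_multiview(
    morgan: FingerprintBlock,
    maccs: FingerprintBlock,
    descriptors: Optional[DescriptorBlock],
) -> MultiViewMatrix:
    blocks = [morgan.bits.astype(float), maccs.bits.astype(float)]
    prov = (["morgan"] * morgan.width) + (["maccs"] * maccs.width)
    names = morgan.column_names() + maccs.column_names()
    if descriptors is not None:
        blocks.append(descriptors.values)
        prov += ["descriptor"] * len(descriptors.names)
        names += list(descriptors.names)
    return MultiViewMatrix(np.column_stack(blocks), np.array(prov), names)


def make_split(
    n_or_labels: Union[int, Sequence[int]],
    labels: Optional[Sequence[int]] = None,
    test_fraction: float = 0.1,
    n_folds: int = 5,
    seed: int = 0,
) -> SplitPlan:
    """Stratified 9:1 train/test split plus 5 stratified CV folds.

    Accepts either ``(labels,)`` or ``(n, labels)``; indices are positions
    into the label vector.
    """
    if labels is None:
        labels = np.asarray(n_or_labels, dtype=int)
    else:
        labels = np.asarray(labels, dtype=int)
        if len(labels) != int(n_or_labels):
            raise ValueError("n does not match labels length")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2 or counts.min() < n_folds:
        raise ValueError(f"need >= {n_folds} compounds per class")
    idx = np.arange(len(labels))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, stratify=labels, random_state=seed)
    train_idx = np.sort(train_idx)
    test_idx = np.sort(test_idx)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = [(train_idx[tr], train_idx[va])
             for tr, va in skf.split(train_idx.reshape(-1, 1), labels[train_idx])]
    return SplitPlan(train_idx, test_idx, folds, seed)


def build_estimator(algorithm: str, config: dict, seed: int = 0,
                    probability: bool = False):
    """Instantiate the sklearn/NumPy estimator for one configuration."""
    if algorithm == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **config)
    if algorithm == "svm":
        svc = SVC(random_state=seed, **config)
        if probability:
            # Platt-style sigmoid calibration for probability outputs
            return CalibratedClassifierCV(svc, method="sigmoid", cv=5,
                                          ensemble=False)
        return svc
    if algorithm == "knn":
        return KNeighborsClassifier(**config)
    if algorithm == "fcnn":
        return FCNNClassifier(random_state=seed, **config)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def enumerate_grid(grid: Dict[str, list]) -> List[dict]:
    """Cartesian product in listed order; index order is the tie-break order."""
    keys = list(grid)
    return [dict(zip(keys, combo))
            for combo in itertools.product(*(grid[k] for k in keys))]


def grid_search_cv(
    algorithm: str,
    grid: Dict[str, list],
    features: np.ndarray,
    labels: Sequence[int],
    plan: SplitPlan,
    seed: int = 0,
) -> Tuple[dict, List[dict]]:
    """Exhaustive grid search scored by mean 5-fold validation accuracy.

    Returns the winning configuration (ties -> first listed) and the full
    per-configuration results ``[{config, mean_accuracy, sd_accuracy}]``.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    results = []
    for cfg in enumerate_grid(grid):
        scores = []
        for tr, va in plan.folds:
            try:
                est = build_estimator(algorithm, cfg, seed)
                est.fit(X[tr], y[tr])
                scores.append(float(np.mean(est.predict(X[va]) == y[va])))
            except Exception as exc:
                warnings.warn(f"config {cfg} failed on a fold: {exc}")
                scores.append(0.0)
        results.append({"config": cfg,
                        "mean_accuracy": float(np.mean(scores)),
                        "sd_accuracy": float(np.std(scores, ddof=1))})
    best_i = int(np.argmax([r["mean_accuracy"] for r in results]))
    return results[best_i]["config"], results


def train_fcnn(
    features: Union[MultiViewMatrix, np.ndarray],
    labels: Sequence[int],
    plan: SplitPlan,
    space: Optional[FcnnSpace] = None,
    budget: int = 30,
    seed: int = 0,
    max_epochs: int = 200,
    patience: int = 20,
) -> Tuple[FCNNClassifier, dict, List[dict]]:
    """Random search over ``space``: each trial is scored by mean fold
    validation accuracy (training with early stopping on the fold's
    validation loss); the best trial is refit on the full training split.

    Returns (fitted network, chosen config, trial log).
    """
    X = features.values if isinstance(features, MultiViewMatrix) else \
        np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    space = space or FcnnSpace()
    rng = np.random.default_rng(seed)
    trials = []
    for t in range(budget):
        cfg = space.sample(rng)
        accs = []
        for tr, va in plan.folds:
            try:
                net = FCNNClassifier(random_state=seed + t,
                                     max_epochs=max_epochs, patience=patience,
                                     validation_fraction=0.0, **cfg)
                net.fit(X[tr], y[tr], X_val=X[va], y_val=y[va])
                accs.append(float(np.mean(net.predict(X[va]) == y[va])))
            except FloatingPointError as exc:
                warnings.warn(f"trial {t} aborted: {exc}")
                accs.append(0.0)
        trials.append({"config": cfg, "mean_accuracy": float(np.mean(accs))})
    best_i = int(np.argmax([t["mean_accuracy"] for t in trials]))
    best_cfg = trials[best_i]["config"]
    final = FCNNClassifier(random_state=seed, max_epochs=max_epochs,
                           patience=patience, **best_cfg)
    final.fit(X[plan.train_idx], y[plan.train_idx])
    return final, best_cfg, trials


@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to apply it."""

    algorithm: str
    view: str
    estimator: object
    hyperparameters: dict
    feature_names: List[str]
    provenance: Optional[np.ndarray] = None   # multiview column tags
    threshold: float = 0.5
    selector_state: Optional[object] = None

    def n_features(self) -> int:
        return len(self.feature_names)

    def feature_summary(self) -> dict:
        if self.provenance is not None:
            views, counts = np.unique(self.provenance, return_counts=True)
            return {v: int(c) for v, c in zip(views, counts)}
        return {self.view: len(self.feature_names)}

    def predict(self, features: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        X = np.asarray(features, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features():
            raise ValueError(
                f"feature width {X.shape[1] if X.ndim == 2 else X.shape} does "
                f"not match the model's {self.view} layout "
                f"({self.n_features()} columns: {self.feature_summary()})")
        proba = self.estimator.predict_proba(X)[:, 1]
        return proba, (proba >= self.threshold).astype(int)

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "view": self.view,
            "hyperparameters": self.hyperparameters,
            "decision_threshold": self.threshold,
            "feature_views": self.feature_summary(),
        }


def predict(model: TrainedModel, features) -> Tuple[np.ndarray, np.ndarray]:
    """Functional facade: (probability vector, class vector)."""
    return model.predict(features)
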