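"""Confusion-matrix metrics, ROC-AUC and Y-randomization.

The five confusion-based metrics are computed literally from their
definitions (positive class = toxic = 1):

    Acc = (TP+TN) / (TP+TN+FP+FN)
    Pre = TP / (TP+FP)
    Spe = TN / (TN+FP)
    Sen = TP / (TP+FN)
    F1  = TP / (TP + 0.5 (FP+FN))

Zero-denominator cases are reported as undefined with a reason rather than
silently NaN. ROC-AUC uses the rank (Mann–Whitney) formulation with tie
averaging. Y-randomization refits the chosen model on permuted training
labels; a genuine structure–activity model must beat every permuted refit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .train import SplitPlan, build_estimator

METRIC_ORDER = ["acc", "auc", "pre", "spe", "sen", "f1"]   # Table column order


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricReport:
    acc: Optional[float] = None
    auc: Optional[float] = None
    pre: Optional[float] = None
    spe: Optional[float] = None
    sen: Optional[float] = None
    f1: Optional[float] = None
    undefined: Dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {m: getattr(self, m) for m in METRIC_ORDER}
        if self.undefined:
            out["undefined"] = dict(self.undefined)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{m.capitalize() if m != "auc" else "AUC":
                              getattr(self, m) for m in METRIC_ORDER}])


def confusion(labels: Sequence[int], predicted: Sequence[int]) -> ConfusionCounts:
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if y.shape != p.shape:
        raise ValueError("labels and predictions differ in length")
    return ConfusionCounts(
        TP=int(np.sum((y == 1) & (p == 1))),
        FP=int(np.sum((y == 0) & (p == 1))),
        TN=int(np.sum((y == 0) & (p == 0))),
        FN=int(np.sum((y == 1) & (p == 0))),
    )


def metrics(c: ConfusionCounts) -> MetricReport:
    """Evaluate the five confusion formulas exactly; AUC left absent."""
    if c.total == 0:
        raise ValueError("empty confusion table")
    rep = MetricReport()
    rep.acc = (c.TP + c.TN) / c.total
    if c.TP + c.FP > 0:
        rep.pre = c.TP / (c.TP + c.FP)
    else:
        rep.undefined["pre"] = "no positive predictions (TP+FP=0)"
    if c.TN + c.FP > 0:
        rep.spe = c.TN / (c.TN + c.FP)
    else:
        rep.undefined["spe"] = "no true negatives in labels (TN+FP=0)"
    if c.TP + c.FN > 0:
        rep.sen = c.TP / (c.TP + c.FN)
    else:
        rep.undefined["sen"] = "no true positives in labels (TP+FN=0)"
    denom = c.TP + 0.5 * (c.FP + c.FN)
    if denom > 0:
        rep.f1 = c.TP / denom
    else:
        rep.undefined["f1"] = "TP, FP and FN all zero"
    return rep


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> Optional[float]:
    """Rank-based AUC with tie averaging; None (flagged) for one-class input."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        warnings.warn("AUC undefined: only one class present")
        return None
    return float(roc_auc_score(y, s))


@dataclass
class YRandResult:
    original_score: float
    permuted_scores: List[float]
    n_permutations: int
    verdict: bool

    def to_dict(self) -> dict:
        return {
            "original_auc": self.original_score,
            "permuted_auc_mean": float(np.mean(self.permuted_scores))
            if self.permuted_scores else None,
            "permuted_auc_max": float(np.max(self.permuted_scores))
            if self.permuted_scores else None,
            "n_permutations": self.n_permutations,
            "original_exceeds_all_permuted": self.verdict,
        }


def _shuffled(rng: np.random.Generator, y: np.ndarray) -> np.ndarray:
    """A permutation of y differing from y (re-drawn if identical, n > 2)."""
    for _ in range(1000):
        perm = rng.permutation(y)
        if len(y) <= 2 or not np.array_equal(perm, y):
            return perm
    return perm  # pragma: no cover - constant label vector


def y_randomization(
    algorithm: str,
    hyperparameters: dict,
    features: np.ndarray,
    labels: Sequence[int],
    plan: SplitPlan,
    n_permutations: int = 10,
    seed: int = 0,
) -> YRandResult:
    """Retrain with permuted training labels; score test-set AUC each time.

    The original model (same algorithm/hyperparameters, unpermuted labels)
    provides the reference score; the verdict is True iff it strictly
    exceeds every permuted score.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)

    def _fit_score(y_train: np.ndarray) -> float:
        est = build_estimator(algorithm, hyperparameters, seed,
                              probability=(algorithm == "svm"))
        est.fit(X[plan.train_idx], y_train)
        proba = est.predict_proba(X[plan.test_idx])[:, 1]
        auc = roc_auc(y[plan.test_idx], proba)
        return auc if auc is not None else 0.5

    original = _fit_score(y[plan.train_idx])
    permuted = [_fit_score(_shuffled(rng, y[plan.train_idx]))
                for _ in range(n_permutations)]
    verdict = all(original > p for p in permuted)
    return YRandResult(original, permuted, n_permutations, verdict)


def full_report(labels, predicted, scores=None) -> MetricReport:
    """Convenience: confusion metrics plus AUC when scores are given."""
    rep = metrics(confusion(labels, predicted))
    if scores is not None:
        auc = roc_auc(labels, scores)
        if auc is None:
            rep.undefined["auc"] = "only one class present"
        else:
            rep.auc = auc
    return rep
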