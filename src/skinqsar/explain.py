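"""Per-prediction additive feature attribution (Shapley values).

The attribution decomposes a prediction into a base value plus one
contribution per feature,

    f(x) = φ0 + Σ_i φ_i,

where φ0 is the expected model output over a background set and φ_i the
Shapley value of feature i. The estimator is model-agnostic: for each
sampled feature permutation and background row, features are switched one
at a time from the background value to the query value, and the change in
model output when feature i switches accumulates into φ_i (telescoping, so
the sum of contributions per sample equals f(x) minus the background
output exactly). For M ≤ 3 features an exact mode enumerates all M!
permutations against the full background, giving the exact Shapley values.

The attribution target is the predicted probability of the toxic class.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd


@dataclass
class AttributionResult:
    phi0: float
    phi: np.ndarray
    fx: float
    residual: float
    feature_names: Optional[List[str]] = None


def _as_predict_fn(model) -> Callable[[np.ndarray], np.ndarray]:
    if callable(model) and not hasattr(model, "predict_proba"):
        return lambda X: np.asarray(model(X), dtype=float).ravel()
    return lambda X: np.asarray(model.predict_proba(X))[:, 1]


def _accumulate(f, x, background_rows, perms) -> np.ndarray:
    """Sum over (perm, background-row) pairs of the telescoping differences.

    For each pair, evaluates the chain b -> ... -> x along the permutation in
    one batched model call of M+1 rows.
    """
    M = x.shape[0]
    phi = np.zeros(M)
    # batch several chains per predict call to amortize model overhead
    chunk = max(1, 16384 // (M + 1))
    for start in range(0, len(perms), chunk):
        group = perms[start:start + chunk]
        rows = []
        for (perm, b) in group:
            chain = np.tile(background_rows[b], (M + 1, 1))
            for step, j in enumerate(perm, start=1):
                chain[step:, j] = x[j]
            rows.append(chain)
        out = f(np.vstack(rows))
        for gi, (perm, b) in enumerate(group):
            vals = out[gi * (M + 1):(gi + 1) * (M + 1)]
            phi[list(perm)] += np.diff(vals)
    return phi


def shapley_attribution(
    model,
    x: np.ndarray,
    background: np.ndarray,
    n_samples: int = 2000,
    seed: int = 0,
    mode: str = "auto",
    feature_names: Optional[List[str]] = None,
) -> AttributionResult:
    """Estimate φ0 and per-feature φ for one query row.

    ``model`` is either an estimator with ``predict_proba`` or a callable
    returning a probability per row. ``mode`` is "sampling", "exact"
    (all M! permutations × all background rows; M ≤ 8 enforced) or "auto"
    (exact when M ≤ 3). Background rows are cycled deterministically in
    sampling mode, so Monte-Carlo error affects the split among features,
    not the additive total, whenever n_samples is a multiple of the
    background size.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    f = _as_predict_fn(model)
    x = np.asarray(x, dtype=float).ravel()
    B = np.atleast_2d(np.asarray(background, dtype=float))
    if B.shape[0] < 1:
        raise ValueError("background must be non-empty")
    M = x.shape[0]
    if B.shape[1] != M:
        raise ValueError("background width must match the query row")

    if mode == "auto":
        mode = "exact" if M <= 3 else "sampling"
    if mode == "exact":
        if M > 8:
            raise ValueError("exact enumeration is limited to M <= 8")
        perms = [(perm, b)
                 for perm in itertools.permutations(range(M))
                 for b in range(B.shape[0])]
    elif mode == "sampling":
        rng = np.random.default_rng(seed)
        perms = [(tuple(rng.permutation(M)), i % B.shape[0])
                 for i in range(n_samples)]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    phi = _accumulate(f, x, B, perms) / len(perms)
    phi0 = float(f(B).mean())
    fx = float(f(x[None, :])[0])
    residual = abs(fx - phi0 - phi.sum())
    return AttributionResult(phi0, phi, fx, residual, feature_names)


def top_features(
    attributions: Sequence[AttributionResult],
    k: int = 20,
    feature_names: Optional[List[str]] = None,
) -> pd.DataFrame:
    """Rank features by mean |φ| over a compound set.

    Returns a frame with the mean absolute contribution, the signed mean,
    and the fraction of compounds pushed toward the toxic class (φ > 0).
    """
    if not attributions:
        raise ValueError("need at least one attribution")
    phis = np.vstack([a.phi for a in attributions])
    names = feature_names or attributions[0].feature_names or \
        [f"f{i}" for i in range(phis.shape[1])]
    mean_abs = np.abs(phis).mean(axis=0)
    order = np.argsort(-mean_abs, kind="stable")[: min(k, phis.shape[1])]
    return pd.DataFrame({
        "feature": [names[i] for i in order],
        "mean_abs_phi": mean_abs[order],
        "mean_phi": phis.mean(axis=0)[order],
        "frac_toward_toxic": (phis > 0).mean(axis=0)[order],
    })


class PermutationShapleyExplainer:
    """Object facade binding a model and background set.

    ``background`` is subsampled (seeded) to at most ``max_background``
    rows, which bounds the per-query cost.
    """

    def __init__(self, model, background: np.ndarray,
                 max_background: int = 100, n_samples: int = 2000,
                 seed: int = 0, feature_names: Optional[List[str]] = None):
        B = np.atleast_2d(np.asarray(background, dtype=float))
        if B.shape[0] > max_background:
            rng = np.random.default_rng(seed)
            B = B[rng.choice(B.shape[0], max_background, replace=False)]
        self.model = model
        self.background = B
        self.n_samples = n_samples
        self.seed = seed
        self.feature_names = feature_names

    def attribute(self, x: np.ndarray, mode: str = "auto") -> AttributionResult:
        return shapley_attribution(self.model, x, self.background,
                                   self.n_samples, self.seed, mode,
                                   self.feature_names)

    def attribute_set(self, X: np.ndarray, mode: str = "auto"
                      ) -> List[AttributionResult]:
        return [self.attribute(row, mode) for row in np.atleast_2d(X)]
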