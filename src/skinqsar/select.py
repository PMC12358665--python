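"""The descriptor-selection cascade.

Four stages, fit on training rows only and frozen for reuse:

1. low-variance filter (sample variance <= threshold removed; default
   threshold 1e-8, i.e. constant-column removal),
2. standardization to mean 0 / sample sd 1 (n-1 convention),
3. one-way ANOVA screen between the two classes (keep p < alpha),
4. L1-penalized linear regression on the 0/1 labels (Lasso); columns whose
   coefficient is exactly zero are dropped. Penalty strength can be a fixed
   value or chosen by 5-fold CV over a log grid ("cv").

The fingerprint views never pass through the cascade — selection applies to
continuous descriptors only. The retained sets are nested:
final (L1) set ⊆ ANOVA set ⊆ variance-filtered set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Union

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.linear_model import Lasso, LassoCV, LogisticRegression

from .featurize import DescriptorBlock, EmptyFeatureError

DEFAULT_VARIANCE_THRESHOLD = 1e-8
DEFAULT_ANOVA_ALPHA = 0.05


@dataclass
class SelectorState:
    retained_after_variance: List[str]
    means: np.ndarray          # per retained_after_variance column
    sds: np.ndarray
    anova_kept: List[str]
    l1_kept: List[str]
    variance_threshold: float
    anova_alpha: float
    l1_strength: float

    def to_dict(self) -> dict:
        return {
            "variance_threshold": self.variance_threshold,
            "anova_alpha": self.anova_alpha,
            "l1_strength": self.l1_strength,
            "n_after_variance": len(self.retained_after_variance),
            "n_after_anova": len(self.anova_kept),
            "n_selected": len(self.l1_kept),
            "selected": list(self.l1_kept),
        }


def low_variance_filter(
    block: DescriptorBlock, threshold: float = DEFAULT_VARIANCE_THRESHOLD
) -> DescriptorBlock:
    """Drop columns with sample variance <= threshold."""
    var = block.values.var(axis=0, ddof=1) if block.values.shape[0] > 1 else \
        np.zeros(block.values.shape[1])
    keep = [n for n, v in zip(block.names, var) if v > threshold]
    if not keep:
        raise EmptyFeatureError("variance filter removed every column")
    return block.subset(keep)


def standardize(
    block: DescriptorBlock,
    means: Optional[np.ndarray] = None,
    sds: Optional[np.ndarray] = None,
):
    """Center/scale columns; fit mode returns (block, means, sds)."""
    if means is None:
        means = block.values.mean(axis=0)
        sds = block.values.std(axis=0, ddof=1)
        if np.any(sds <= 0):
            raise ValueError("zero-variance column reached standardization")
        out = DescriptorBlock((block.values - means) / sds, block.names, block.row_ids)
        return out, means, sds
    return DescriptorBlock((block.values - means) / sds, block.names, block.row_ids)


def anova_screen(
    block: DescriptorBlock, labels: np.ndarray, alpha: float = DEFAULT_ANOVA_ALPHA
) -> List[str]:
    """One-way F test per column between the two classes; keep p < alpha."""
    labels = np.asarray(labels, dtype=int)
    g0, g1 = block.values[labels == 0], block.values[labels == 1]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("each class needs >= 2 samples for the ANOVA screen")
    _, p = stats.f_oneway(g0, g1)
    return [n for n, pv in zip(block.names, p) if np.isfinite(pv) and pv < alpha]


def l1_select(
    block: DescriptorBlock,
    labels: np.ndarray,
    strength: Union[float, str] = "cv",
    seed: int = 0,
) -> tuple:
    """Lasso on 0/1 labels; returns (kept names, fitted strength).

    ``strength="cv"`` picks the penalty by 5-fold CV over a log grid.
    """
    y = np.asarray(labels, dtype=float)
    if strength == "cv":
        model = LassoCV(alphas=np.logspace(-4, 0, 25), cv=5, random_state=seed,
                        max_iter=50_000)
        model.fit(block.values, y)
        alpha = float(model.alpha_)
        coef = model.coef_
    else:
        alpha = float(strength)
        if alpha == 0.0:
            coef = np.linalg.lstsq(
                np.column_stack([block.values, np.ones(len(y))]), y, rcond=None
            )[0][:-1]
        else:
            model = Lasso(alpha=alpha, max_iter=50_000)
            model.fit(block.values, y)
            coef = model.coef_
    kept = [n for n, c in zip(block.names, coef) if c != 0.0]
    if not kept:
        raise EmptyFeatureError("L1 selection zeroed every coefficient")
    return kept, alpha


class DescriptorSelectionCascade(BaseEstimator, TransformerMixin):
    """sklearn transformer wrapping the four-stage cascade.

    ``fit`` consumes a cleaned :class:`DescriptorBlock` plus binary labels;
    ``transform`` reproduces the identical column subset and scaling on any
    block carrying (at least) the fitted columns. Fitted state lives in
    ``state_``.
    """

    def __init__(
        self,
        variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
        anova_alpha: float = DEFAULT_ANOVA_ALPHA,
        l1_strength: Union[float, str] = "cv",
        random_state: int = 0,
    ):
        self.variance_threshold = variance_threshold
        self.anova_alpha = anova_alpha
        self.l1_strength = l1_strength
        self.random_state = random_state

    def fit(self, block: DescriptorBlock, y: np.ndarray):
        y = np.asarray(y, dtype=int)
        filtered = low_variance_filter(block, self.variance_threshold)
        scaled, means, sds = standardize(filtered)
        anova_kept = anova_screen(scaled, y, self.anova_alpha)
        if not anova_kept:
            raise EmptyFeatureError("ANOVA screen removed every column")
        l1_kept, alpha = l1_select(scaled.subset(anova_kept), y,
                                   self.l1_strength, self.random_state)
        self.state_ = SelectorState(
            retained_after_variance=list(filtered.names),
            means=means, sds=sds,
            anova_kept=anova_kept, l1_kept=l1_kept,
            variance_threshold=self.variance_threshold,
            anova_alpha=self.anova_alpha, l1_strength=alpha,
        )
        return self

    def transform(self, block: DescriptorBlock) -> DescriptorBlock:
        st = self.state_
        sub = block.subset(st.retained_after_variance)
        bad = ~np.isfinite(sub.values)
        if bad.any():
            # query compound missing a retained descriptor: training-mean
            # imputation keeps single-compound prediction possible
            import warnings
            warnings.warn(f"{int(bad.sum())} missing descriptor value(s) "
                          "imputed with training means")
            values = np.where(bad, np.broadcast_to(st.means, sub.values.shape),
                              sub.values)
            sub = DescriptorBlock(values, sub.names, sub.row_ids)
        scaled = standardize(sub, st.means, st.sds)
        return scaled.subset(st.l1_kept)


def fit_cascade(block: DescriptorBlock, labels, **kwargs) -> SelectorState:
    return DescriptorSelectionCascade(**kwargs).fit(block, labels).state_


def apply_cascade(block: DescriptorBlock, state: SelectorState) -> DescriptorBlock:
    cascade = DescriptorSelectionCascade()
    cascade.state_ = state
    return cascade.transform(block)
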