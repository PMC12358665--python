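"""Applicability-domain gating.

Three complementary domain definitions, combined by consensus:

* **Euclidean centroid AD** (descriptor view): the centroid is the per-column
  mean of the scaled training descriptors; the threshold ``dt`` is the
  largest training-compound distance to that centroid. A query is inside iff
  its distance does not exceed ``dt`` — so every training compound is inside
  its own domain by construction.
* **Tanimoto AD** (one per fingerprint view): from the mean γ̄ and sample
  standard deviation σ of Tanimoto similarity over all distinct training
  pairs, the threshold is ST = γ̄ + Z·σ. A query is inside iff the mean
  similarity to its k nearest training fingerprints strictly exceeds ST.
* **Consensus**: with all three views present, a compound is inside the
  domain iff at least two view verdicts agree it is; a single-view model
  inherits that view's verdict; with exactly two views both must agree.

Tanimoto similarity of an all-zero fingerprint with anything is defined as
0 (conservative: featureless queries fall outside). ST may exceed 1 for a
tight training set, in which case nothing — not even a training duplicate —
can be inside that view; this is left uncapped but warned about.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from sklearn.base import BaseEstimator

from .featurize import DescriptorBlock, FingerprintBlock


def tanimoto_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto |A∩B|/|A∪B| between rows of two 0/1 matrices."""
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    inter = A @ B.T
    union = A.sum(1)[:, None] + B.sum(1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    return sim


class EuclideanApplicabilityDomain(BaseEstimator):
    """Centroid-distance AD over scaled descriptors.

    Fitted attributes: ``centroid_`` (column means), ``dt_`` (max training
    distance), ``dimension_``.
    """

    def fit(self, X: np.ndarray, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 1:
            raise ValueError("need at least one training row")
        if not np.isfinite(X).all():
            raise ValueError("training descriptors must be finite")
        self.centroid_ = X.mean(axis=0)
        self.dt_ = float(np.max(np.linalg.norm(X - self.centroid_, axis=1)))
        self.dimension_ = X.shape[1]
        return self

    def distances(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.dimension_:
            raise ValueError(
                f"expected {self.dimension_} descriptor columns, got {X.shape[1]}")
        return np.linalg.norm(X - self.centroid_, axis=1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """True per query iff its centroid distance <= dt."""
        return self.distances(X) <= self.dt_


class TanimotoApplicabilityDomain(BaseEstimator):
    """Similarity-threshold AD over one fingerprint view.

    Parameters: ``Z`` significance multiplier, ``k`` neighbor count.
    Fitted attributes: ``gamma_bar_`` (γ̄), ``sigma_`` (σ over distinct
    pairs, sample sd), ``st_`` (γ̄ + Zσ), ``train_fp_``.
    """

    def __init__(self, Z: float = 0.5, k: int = 5):
        self.Z = Z
        self.k = k

    def fit(self, fingerprints: np.ndarray, y=None):
        F = np.asarray(fingerprints)
        if F.ndim != 2 or F.shape[0] < 2:
            raise ValueError("need at least two training fingerprints")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        sim = tanimoto_matrix(F, F)
        iu = np.triu_indices(F.shape[0], k=1)   # distinct pairs only
        pair_sims = sim[iu]
        self.gamma_bar_ = float(pair_sims.mean())
        self.sigma_ = float(pair_sims.std(ddof=1)) if pair_sims.size > 1 else 0.0
        self.st_ = self.gamma_bar_ + self.Z * self.sigma_
        self.train_fp_ = F.astype(np.uint8)
        if self.st_ >= 1.0:
            warnings.warn(
                f"Tanimoto AD threshold ST={self.st_:.3f} >= 1: no query "
                "(even a training duplicate) can fall inside this view")
        return self

    def neighbor_similarity(self, fingerprints: np.ndarray) -> np.ndarray:
        """Mean similarity of each query to its k nearest training rows."""
        Q = np.asarray(fingerprints)
        k = min(self.k, self.train_fp_.shape[0])
        sim = tanimoto_matrix(Q, self.train_fp_)
        top = np.sort(sim, axis=1)[:, -k:]
        return top.mean(axis=1)

    def predict(self, fingerprints: np.ndarray) -> np.ndarray:
        """True per query iff mean top-k similarity strictly exceeds ST."""
        return self.neighbor_similarity(fingerprints) > self.st_


@dataclass
class ADVerdict:
    euclid_in: Optional[bool] = None
    maccs_in: Optional[bool] = None
    morgan_in: Optional[bool] = None
    consensus_in: bool = False


def consensus(
    euclid_in: Optional[bool] = None,
    maccs_in: Optional[bool] = None,
    morgan_in: Optional[bool] = None,
) -> ADVerdict:
    """Majority rule over the available view verdicts (2-of-3)."""
    present = [v for v in (euclid_in, maccs_in, morgan_in) if v is not None]
    if not present:
        raise ValueError("at least one view verdict is required")
    if len(present) == 1:
        cons = present[0]
    else:
        cons = sum(present) >= 2
    return ADVerdict(euclid_in, maccs_in, morgan_in, bool(cons))


@dataclass
class ADBundle:
    """All fitted AD models for one trained classifier."""

    euclidean: Optional[EuclideanApplicabilityDomain] = None
    tanimoto_maccs: Optional[TanimotoApplicabilityDomain] = None
    tanimoto_morgan: Optional[TanimotoApplicabilityDomain] = None

    def verdicts(
        self,
        descriptors: Optional[np.ndarray] = None,
        maccs: Optional[np.ndarray] = None,
        morgan: Optional[np.ndarray] = None,
    ) -> List[ADVerdict]:
        parts = {}
        n = None
        if self.euclidean is not None and descriptors is not None:
            parts["euclid_in"] = self.euclidean.predict(descriptors)
            n = len(parts["euclid_in"])
        if self.tanimoto_maccs is not None and maccs is not None:
            parts["maccs_in"] = self.tanimoto_maccs.predict(maccs)
            n = len(parts["maccs_in"])
        if self.tanimoto_morgan is not None and morgan is not None:
            parts["morgan_in"] = self.tanimoto_morgan.predict(morgan)
            n = len(parts["morgan_in"])
        if n is None:
            raise ValueError("no AD view available for the given inputs")
        return [
            consensus(**{k: bool(v[i]) for k, v in parts.items()})
            for i in range(n)
        ]

    def to_dict(self) -> dict:
        out: dict = {}
        if self.euclidean is not None:
            out["euclidean"] = {"dt": self.euclidean.dt_,
                                "dimension": self.euclidean.dimension_}
        for name, model in (("maccs", self.tanimoto_maccs),
                            ("morgan", self.tanimoto_morgan)):
            if model is not None:
                out[f"tanimoto_{name}"] = {
                    "gamma_bar": model.gamma_bar_, "sigma": model.sigma_,
                    "Z": model.Z, "ST": model.st_, "k": model.k,
                }
        out["consensus_rule"] = "inside if >= 2 of the available view verdicts"
        return out


# ---------------------------------------------------------------------------
# functional facades

def fit_euclidean_ad(train_descriptors: DescriptorBlock) -> EuclideanApplicabilityDomain:
    return EuclideanApplicabilityDomain().fit(train_descriptors.values)


def euclidean_inside(model: EuclideanApplicabilityDomain, query) -> np.ndarray:
    values = query.values if isinstance(query, DescriptorBlock) else query
    return model.predict(values)


def fit_tanimoto_ad(train_fp: FingerprintBlock, Z: float = 0.5,
                    k: int = 5) -> TanimotoApplicabilityDomain:
    return TanimotoApplicabilityDomain(Z=Z, k=k).fit(train_fp.bits)


def tanimoto_inside(model: TanimotoApplicabilityDomain, query_fp,
                    k: Optional[int] = None) -> np.ndarray:
    bits = query_fp.bits if isinstance(query_fp, FingerprintBlock) else query_fp
    if k is not None:
        if k < 1:
            raise ValueError("k must be >= 1")
        model = TanimotoApplicabilityDomain(Z=model.Z, k=k).fit(model.train_fp_)
    return model.predict(bits)
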