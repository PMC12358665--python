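"""Cluster-representative under-sampling of the majority class.

The majority class is grouped into k clusters (k = minority-class size) by
k-means on the 2048-bit circular fingerprints treated as 0/1 real vectors,
and one representative per cluster — the member nearest its centroid in
Euclidean distance, input order breaking ties — is retained. The balanced
output is all minority compounds plus the k representatives, so both classes
end up exactly the minority size while the retained majority compounds still
tile the majority's chemical space. Minority compounds are never touched.

If clustering yields fewer than k non-empty clusters (possible when the
majority set has fewer than k distinct fingerprints), the shortfall is
filled by the globally nearest unselected majority compounds to their own
cluster centroids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .featurize import FingerprintBlock
from .records import MoleculeRecord


@dataclass
class BalancePlan:
    kept_ids: List[str]
    removed_ids: List[str]
    k_clusters: int
    seed: int
    cluster_of: dict = field(default_factory=dict)  # majority id -> cluster idx

    def to_frame(self) -> pd.DataFrame:
        rows = [{"id": i, "status": "kept", "cluster": self.cluster_of.get(i, -1)}
                for i in self.kept_ids]
        rows += [{"id": i, "status": "removed", "cluster": self.cluster_of.get(i, -1)}
                 for i in self.removed_ids]
        return pd.DataFrame(rows, columns=["id", "status", "cluster"])


class ClusterUndersampler(BaseEstimator):
    """k-means representative under-sampler (imblearn-style ``fit_resample``).

    Parameters
    ----------
    random_state : int
        Seed for k-means++ initialization; the plan is bit-reproducible.
    n_init : int
        Number of k-means restarts (1 keeps the large presets fast).
    """

    def __init__(self, random_state: int = 0, n_init: int = 1):
        self.random_state = random_state
        self.n_init = n_init

    def fit_resample(
        self,
        records: Sequence[MoleculeRecord],
        fingerprints: FingerprintBlock,
    ) -> Tuple[List[MoleculeRecord], BalancePlan]:
        if fingerprints.kind != "morgan":
            raise ValueError("under-sampling clusters on the morgan view")
        ids = [r.id for r in records]
        if fingerprints.row_ids != ids:
            raise ValueError("fingerprint rows are not aligned with records")
        labels = np.array([r.label for r in records], dtype=object)
        if any(l is None for l in labels):
            raise ValueError("all records must be labeled for balancing")
        labels = labels.astype(int)

        n1, n0 = int((labels == 1).sum()), int((labels == 0).sum())
        if n1 == 0 or n0 == 0:
            raise ValueError("both classes must be present")
        minority_class = 1 if n1 <= n0 else 0
        k = min(n1, n0)
        maj_idx = np.flatnonzero(labels != minority_class)
        min_idx = np.flatnonzero(labels == minority_class)

        if len(maj_idx) == k:  # already balanced
            plan = BalancePlan(kept_ids=[ids[i] for i in maj_idx],
                               removed_ids=[], k_clusters=k,
                               seed=self.random_state)
            return list(records), plan

        X = fingerprints.bits[maj_idx].astype(np.float64)
        km = KMeans(n_clusters=k, init="k-means++", n_init=self.n_init,
                    random_state=self.random_state)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # duplicate points can warn
            assign = km.fit_predict(X)
        centroids = km.cluster_centers_
        # distance of each majority compound to its own centroid
        dist_own = np.linalg.norm(X - centroids[assign], axis=1)

        kept_local: List[int] = []
        for c in range(k):
            members = np.flatnonzero(assign == c)
            if members.size == 0:
                continue
            best = members[np.argmin(dist_own[members])]  # argmin keeps first tie
            kept_local.append(int(best))
        if len(kept_local) < k:  # shortfall fill: globally nearest unselected
            chosen = set(kept_local)
            order = np.argsort(dist_own, kind="stable")
            for j in order:
                if len(kept_local) == k:
                    break
                if int(j) not in chosen:
                    kept_local.append(int(j))
                    chosen.add(int(j))

        kept_set = set(kept_local)
        kept_global = sorted(maj_idx[j] for j in kept_local)
        removed_global = [i for j, i in enumerate(maj_idx) if j not in kept_set]
        plan = BalancePlan(
            kept_ids=[ids[i] for i in kept_global],
            removed_ids=[ids[i] for i in removed_global],
            k_clusters=k,
            seed=self.random_state,
            cluster_of={ids[maj_idx[j]]: int(assign[j]) for j in range(len(maj_idx))},
        )
        keep_global = sorted(set(kept_global) | set(int(i) for i in min_idx))
        balanced = [records[i] for i in keep_global]
        return balanced, plan


def cluster_undersample(
    records: Sequence[MoleculeRecord],
    fingerprints: FingerprintBlock,
    seed: int = 0,
) -> Tuple[List[MoleculeRecord], BalancePlan]:
    """Functional facade over :class:`ClusterUndersampler`."""
    return ClusterUndersampler(random_state=seed).fit_resample(records, fingerprints)
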