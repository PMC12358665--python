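"""End-to-end orchestration: train, predict, validate, persist.

This is the layer the CLI calls. A :class:`RunConfig` captures every choice
of a training run (endpoint, view, algorithm, grids, seeds, AD parameters);
:func:`train_endpoint` executes the full protocol —

    optional cluster under-sampling -> featurization (three views) ->
    stratified 9:1 split -> descriptor-selection cascade (fit on the
    training rows only) -> grid / random hyperparameter search over the
    5 CV folds -> final fit -> test-set evaluation -> applicability-domain
    fitting -> optional Y-randomization

— and returns a :class:`ModelBundle` that can be saved to a single archive
file, reloaded, and applied to new compounds.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import joblib
import numpy as np
import yaml

from . import addomain, balance, chemio, evaluate, featurize, select, train
from .records import MoleculeRecord, PredictionRecord


def get_provider(name: str):
    if name == "toy":
        return featurize.ToyDescriptorProvider()
    if name == "rdkit2d":
        return featurize.RDKit2DDescriptorProvider()
    raise ValueError(f"unknown descriptor provider {name!r}")


@dataclass
class RunConfig:
    endpoint: str = "sensitization"
    view: str = "multiview"
    algorithm: str = "rf"
    balance: bool = False
    test_fraction: float = 0.1
    n_folds: int = 5
    seed: int = 0
    descriptor_provider: str = "toy"
    grids: dict = field(default_factory=lambda: copy.deepcopy(train.DEFAULT_GRIDS))
    fcnn_budget: int = 30
    fcnn_max_epochs: int = 200
    fcnn_patience: int = 20
    fcnn_space: dict = field(default_factory=dict)
    ad_z: float = 0.5
    ad_k: int = 5
    variance_threshold: float = select.DEFAULT_VARIANCE_THRESHOLD
    anova_alpha: float = select.DEFAULT_ANOVA_ALPHA
    l1_strength: object = "cv"
    y_randomization: int = 0

    def __post_init__(self) -> None:
        if self.view not in train.VIEWS:
            raise ValueError(f"unknown view {self.view!r}")
        if self.algorithm not in train.ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class ModelBundle:
    endpoint: str
    model: train.TrainedModel
    ad: addomain.ADBundle
    config: RunConfig
    training_smiles: List[str]
    cascade: Optional[select.DescriptorSelectionCascade] = None

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ModelBundle":
        bundle = joblib.load(path)
        if not isinstance(bundle, ModelBundle):
            raise ValueError(f"{path} is not a skinqsar model archive")
        return bundle


@dataclass
class TrainingRun:
    bundle: ModelBundle
    metrics: evaluate.MetricReport
    plan: train.SplitPlan
    balance_plan: Optional[balance.BalancePlan]
    search_results: list
    yrand: Optional[evaluate.YRandResult]
    log: List[str]


def _featurize_all(records, provider, need_descriptors: bool):
    morgan = featurize.morgan_fingerprint(records)
    maccs = featurize.maccs_fingerprint(records)
    clean = None
    if need_descriptors:
        raw = featurize.compute_descriptors(records, provider)
        clean = featurize.drop_missing_descriptors(raw)
    return morgan, maccs, clean


def _assemble_features(view, morgan, maccs, desc_selected):
    if view == "morgan":
        return morgan.bits.astype(float), morgan.column_names(), None
    if view == "maccs":
        return maccs.bits.astype(float), maccs.column_names(), None
    if view == "descriptors":
        return desc_selected.values, list(desc_selected.names), None
    mv = train.build_multiview(morgan, maccs, desc_selected)
    return mv.values, mv.names, mv.provenance


def train_endpoint(records: Sequence[MoleculeRecord],
                   cfg: RunConfig) -> TrainingRun:
    log: List[str] = []
    records = list(records)
    if any(r.label is None for r in records):
        raise ValueError("training requires labels on every compound")
    log.append(f"input: {len(records)} labeled compounds")

    balance_plan = None
    if cfg.balance:
        fp = featurize.morgan_fingerprint(records)
        records, balance_plan = balance.cluster_undersample(records, fp, cfg.seed)
        log.append(f"balanced: {len(records)} compounds "
                   f"({balance_plan.k_clusters} per class)")

    y = np.array([r.label for r in records], dtype=int)
    need_desc = cfg.view in ("descriptors", "multiview")
    provider = get_provider(cfg.descriptor_provider)
    morgan, maccs, clean = _featurize_all(records, provider, need_desc)

    plan = train.make_split(y, test_fraction=cfg.test_fraction,
                            n_folds=cfg.n_folds, seed=cfg.seed)
    log.append(f"split: {len(plan.train_idx)} train / {len(plan.test_idx)} test")

    cascade = None
    desc_selected = None
    if need_desc:
        cascade = select.DescriptorSelectionCascade(
            variance_threshold=cfg.variance_threshold,
            anova_alpha=cfg.anova_alpha,
            l1_strength=cfg.l1_strength,
            random_state=cfg.seed,
        ).fit(clean.take(plan.train_idx), y[plan.train_idx])
        desc_selected = cascade.transform(clean)
        log.append(f"descriptor cascade retained "
                   f"{len(cascade.state_.l1_kept)} descriptors")

    X, names, provenance = _assemble_features(cfg.view, morgan, maccs,
                                              desc_selected)

    if cfg.algorithm == "fcnn":
        space = train.FcnnSpace(**cfg.fcnn_space)
        est, best_cfg, results = train.train_fcnn(
            X, y, plan, space, budget=cfg.fcnn_budget, seed=cfg.seed,
            max_epochs=cfg.fcnn_max_epochs, patience=cfg.fcnn_patience)
    else:
        best_cfg, results = train.grid_search_cv(
            cfg.algorithm, cfg.grids[cfg.algorithm], X, y, plan, cfg.seed)
        est = train.build_estimator(cfg.algorithm, best_cfg, cfg.seed,
                                    probability=(cfg.algorithm == "svm"))
        est.fit(X[plan.train_idx], y[plan.train_idx])
    log.append(f"chosen hyperparameters: {best_cfg}")

    model = train.TrainedModel(
        algorithm=cfg.algorithm, view=cfg.view, estimator=est,
        hyperparameters=best_cfg, feature_names=names,
        provenance=provenance,
        selector_state=cascade.state_ if cascade else None,
    )

    proba, pred = model.predict(X[plan.test_idx])
    report = evaluate.full_report(y[plan.test_idx], pred, proba)
    log.append(f"test metrics: {report.to_dict()}")

    ad = addomain.ADBundle()
    if need_desc:
        ad.euclidean = addomain.EuclideanApplicabilityDomain().fit(
            desc_selected.values[plan.train_idx])
    if cfg.view in ("maccs", "multiview"):
        ad.tanimoto_maccs = addomain.TanimotoApplicabilityDomain(
            Z=cfg.ad_z, k=cfg.ad_k).fit(maccs.bits[plan.train_idx])
    if cfg.view in ("morgan", "multiview"):
        ad.tanimoto_morgan = addomain.TanimotoApplicabilityDomain(
            Z=cfg.ad_z, k=cfg.ad_k).fit(morgan.bits[plan.train_idx])

    yrand = None
    if cfg.y_randomization > 0:
        yrand = evaluate.y_randomization(
            cfg.algorithm, best_cfg, X, y, plan,
            n_permutations=cfg.y_randomization, seed=cfg.seed)
        log.append(f"y-randomization: {yrand.to_dict()}")

    training_smiles = [records[i].smiles for i in plan.train_idx]
    bundle = ModelBundle(endpoint=cfg.endpoint, model=model, ad=ad,
                         config=cfg, training_smiles=training_smiles,
                         cascade=cascade)
    return TrainingRun(bundle, report, plan, balance_plan, results, yrand, log)


def predict_records(
    bundle: ModelBundle, records: Sequence[MoleculeRecord]
) -> Tuple[List[PredictionRecord], List[addomain.ADVerdict]]:
    cfg = bundle.config
    need_desc = cfg.view in ("descriptors", "multiview")
    provider = get_provider(cfg.descriptor_provider)
    morgan, maccs, clean = _featurize_all(records, provider, need_desc)
    desc_selected = bundle.cascade.transform(clean) if need_desc else None
    X, _, _ = _assemble_features(cfg.view, morgan, maccs, desc_selected)
    proba, pred = bundle.model.predict(X)
    verdicts = bundle.ad.verdicts(
        descriptors=desc_selected.values if need_desc else None,
        maccs=maccs.bits if cfg.view in ("maccs", "multiview") else None,
        morgan=morgan.bits if cfg.view in ("morgan", "multiview") else None,
    )
    preds = [
        PredictionRecord(id=r.id, endpoint=bundle.endpoint,
                         predicted_class=int(c), probability=float(p),
                         reliable=v.consensus_in)
        for r, p, c, v in zip(records, proba, pred, verdicts)
    ]
    return preds, verdicts


def validate_external(
    bundle: ModelBundle, records: Sequence[MoleculeRecord]
) -> dict:
    """Sensitivity-focused evaluation on an external labeled list.

    Compounds whose canonical SMILES overlap the training set are excluded
    (with a warning carrying the count) before evaluation.
    """
    if any(r.label is None for r in records):
        raise ValueError("external validation requires labels")
    train_set = set(bundle.training_smiles)
    kept = [r for r in records if r.smiles not in train_set]
    n_overlap = len(records) - len(kept)
    if n_overlap:
        warnings.warn(f"{n_overlap} external compound(s) overlap the "
                      "training set and were excluded")
    if not kept:
        raise ValueError("no external compounds left after overlap removal")
    preds, verdicts = predict_records(bundle, kept)
    y = np.array([r.label for r in kept], dtype=int)
    p = np.array([pr.predicted_class for pr in preds], dtype=int)
    scores = np.array([pr.probability for pr in preds], dtype=float)
    c = evaluate.confusion(y, p)
    report = evaluate.metrics(c)
    if len(np.unique(y)) == 2:
        report.auc = evaluate.roc_auc(y, scores)
    return {
        "n_external": len(records),
        "n_overlap_excluded": n_overlap,
        "n_evaluated": len(kept),
        "sensitivity": report.sen,
        "metrics": report.to_dict(),
        "n_inside_ad": int(sum(v.consensus_in for v in verdicts)),
        "predictions": preds,
    }
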