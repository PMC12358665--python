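# skinqsar

Multi-view QSAR classification of skin-toxicity endpoints — skin
sensitization, skin irritation/corrosion, and acute dermal toxicity — with
applicability-domain gating and per-feature Shapley attribution.

## Who this is for

Early-stage safety screeners who need binary toxicity calls
(toxic / non-toxic under the GHS-derived binarization of each endpoint) for
candidate compounds, together with an honest statement of whether each
prediction can be trusted (is the query inside the model's chemical space?)
and which structural features drove it.

## The method

Each compound is represented by three complementary views:

* **Morgan fingerprint** — radius-2 circular environments hashed to 2048
  binary bits (ECFP4-style);
* **MACCS keys** — the 166-entry substructure dictionary;
* **2-D descriptor panel** — continuous physicochemical descriptors,
  cleaned (any column with a missing value is removed) and reduced by a
  four-stage cascade: low-variance filter → standardization →
  per-descriptor one-way ANOVA screen (keep p < α) → L1-penalized linear
  regression on the 0/1 labels, keeping descriptors with nonzero
  coefficients.

Class imbalance is handled by **cluster-representative under-sampling**:
majority-class compounds are grouped into k = (minority size) k-means
clusters on their Morgan fingerprints and the member nearest each centroid
is kept, so both classes end up equal in size while the retained majority
still covers its chemical space.

Models: random forest, SVM and kNN, tuned by exhaustive grid search
(24 / 16 / 20 configurations), plus a two-hidden-layer fully connected
network (dense → batchnorm → ReLU → dropout, twice, then a sigmoid head;
Adam, binary cross-entropy, early stopping) on the concatenated multi-view
vector, tuned by seeded random search over a bounded space. All selection
uses stratified 9:1 train/test partitioning with 5-fold stratified CV and
mean validation accuracy as the objective. Performance is reported as
Acc, AUC-ROC, Pre, Spe, Sen and F1 from the confusion table, and model
validity is checked by **Y-randomization** (the real model must beat every
label-permuted refit).

Prediction reliability uses a **2-of-3 consensus applicability domain**:

* Euclidean AD — distance to the training centroid in scaled descriptor
  space, thresholded at the largest training distance d_t;
* Tanimoto AD (one per fingerprint view) — mean similarity to the k nearest
  training compounds must exceed S_T = γ̄ + Z·σ, where γ̄ and σ are the
  mean and standard deviation of training pairwise Tanimoto similarity.

Each prediction is decomposed as f(x) = φ₀ + Σᵢ φᵢ by a model-agnostic
permutation Shapley estimator (exact enumeration for ≤ 3 features), and
features are ranked by mean |φ| across a compound set.

A seeded synthetic-library generator (`skinqsar.synthdata`) plants
toxicophore substructures (aromatic nitro, acrylate, thiol) whose presence
raises the toxicity probability from 0.1 to 0.9, so the whole pipeline is
testable end to end without external data.

## Worked example

```python
from skinqsar import synthdata, workflow

records = synthdata.generate_library(
    synthdata.SynthConfig(n_toxic=60, n_nontoxic=60, seed=21))
cfg = workflow.RunConfig(endpoint="irritation", view="multiview",
                         algorithm="rf", seed=3, l1_strength=0.01,
                         grids={"rf": {"n_estimators": [50, 100],
                                       "max_depth": [None, 10],
                                       "min_samples_split": [2]}},
                         y_randomization=5)
run = workflow.train_endpoint(records, cfg)
for line in run.log:
    print("[train]", line)
```

prints

```
[train] input: 120 labeled compounds
[train] split: 108 train / 12 test
[train] descriptor cascade retained 7 descriptors
[train] chosen hyperparameters: {'n_estimators': 50, 'max_depth': None, 'min_samples_split': 2}
[train] test metrics: {'acc': 0.8333, 'auc': 0.75, 'pre': 0.8333, 'spe': 0.8333, 'sen': 0.8333, 'f1': 0.8333}
[train] y-randomization: {'original_auc': 0.75, 'permuted_auc_mean': 0.575, 'permuted_auc_max': 0.6806, 'n_permutations': 5, 'original_exceeds_all_permuted': True}
```

The cascade kept 7 of the 20 descriptors; the tuned forest classifies the
12 held-out compounds at 83% accuracy, and the unpermuted model's AUC
(0.75) beats all five label-permuted refits (mean 0.575) — the model
learned a real structure–activity relation, not noise. Predictions carry
the consensus AD flag:

```python
preds, _ = workflow.predict_records(run.bundle, records[:3])
# PredictionRecord(id='syn00058', endpoint='irritation',
#                  predicted_class=1, probability=0.98, reliable=True)
```

The same workflow is available from the shell:

```bash
skinqsar train    --config cfg.yaml --input library.csv --out-dir out/
skinqsar predict  --model out/model.bundle --input query.csv --out preds.csv
skinqsar validate --model out/model.bundle --input external.csv
```

`train` writes a model archive, a model-card JSON (algorithm,
hyperparameters, AD thresholds d_t / γ̄ / σ / S_T / Z / k, all six metrics)
and a metrics CSV; `validate` reports sensitivity on an external list after
excluding compounds that overlap the training set.

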