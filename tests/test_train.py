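"""Splitting, grid search, the FCNN and multi-view assembly."""

import numpy as np
import pytest
from sklearn.neighbors import KNeighborsClassifier

from skinqsar import train
from skinqsar.fcnn import EarlyStopping, FCNNClassifier
from skinqsar.featurize import DescriptorBlock, FingerprintBlock


class TestMakeSplit:
    def test_stratified_9_1_counts(self, rng):
        y = np.array([1] * 481 + [0] * 519)
        rng.shuffle(y)
        plan = train.make_split(y, seed=0)
        assert len(plan.train_idx) == 900 and len(plan.test_idx) == 100
        test_pos = y[plan.test_idx].sum()
        assert abs(test_pos - 48.1) <= 1
        assert not set(plan.train_idx) & set(plan.test_idx)

    def test_folds_partition_training_rows(self, rng):
        y = rng.integers(0, 2, 120)
        plan = train.make_split(y, seed=1)
        val_union = np.concatenate([va for _, va in plan.folds])
        assert sorted(val_union.tolist()) == sorted(plan.train_idx.tolist())
        for tr, va in plan.folds:
            assert not set(tr) & set(va)
            assert set(tr) | set(va) == set(plan.train_idx.tolist())

    def test_fold_class_balance_within_one(self, rng):
        y = rng.integers(0, 2, 200)
        plan = train.make_split(y, seed=2)
        global_frac = y[plan.train_idx].mean()
        for _, va in plan.folds:
            assert abs(y[va].sum() - global_frac * len(va)) <= 1

    def test_seed_controls_plan(self, rng):
        y = rng.integers(0, 2, 100)
        p1, p2 = train.make_split(y, seed=5), train.make_split(y, seed=5)
        p3 = train.make_split(y, seed=6)
        assert np.array_equal(p1.test_idx, p2.test_idx)
        assert not np.array_equal(p1.test_idx, p3.test_idx)

    def test_too_few_per_class(self):
        with pytest.raises(ValueError):
            train.make_split(np.array([0, 0, 0, 1, 1, 1]))


class TestGrids:
    def test_cartesian_product_sizes(self):
        assert len(train.enumerate_grid(train.DEFAULT_GRIDS["rf"])) == 24
        assert len(train.enumerate_grid(train.DEFAULT_GRIDS["svm"])) == 16
        assert len(train.enumerate_grid(train.DEFAULT_GRIDS["knn"])) == 20

    def test_single_config_grid_returned(self, rng):
        y = rng.integers(0, 2, 60)
        X = rng.normal(0, 1, (60, 5)) + y[:, None]
        plan = train.make_split(y, seed=0)
        grid = {"n_neighbors": [3], "weights": ["uniform"],
                "metric": ["euclidean"]}
        best, results = train.grid_search_cv("knn", grid, X, y, plan)
        assert best == {"n_neighbors": 3, "weights": "uniform",
                        "metric": "euclidean"}
        assert len(results) == 1

    def test_winner_matches_exhaustive_oracle(self, rng):
        """Package grid search equals an independent re-evaluation of every
        configuration with first-listed tie-breaking."""
        y = rng.integers(0, 2, 80)
        X = rng.normal(0, 1, (80, 6)) + 0.8 * y[:, None]
        plan = train.make_split(y, seed=3)
        grid = {"n_neighbors": [1, 3, 5], "weights": ["uniform", "distance"],
                "metric": ["euclidean"]}
        best, results = train.grid_search_cv("knn", grid, X, y, plan)
        oracle = []
        for cfg in train.enumerate_grid(grid):
            accs = []
            for tr, va in plan.folds:
                est = KNeighborsClassifier(**cfg).fit(X[tr], y[tr])
                accs.append(np.mean(est.predict(X[va]) == y[va]))
            oracle.append(float(np.mean(accs)))
        assert [r["mean_accuracy"] for r in results] == pytest.approx(oracle)
        assert best == train.enumerate_grid(grid)[int(np.argmax(oracle))]

    def test_separable_toy_svm_perfect_fold_accuracy(self, rng):
        y = np.repeat([0, 1], 40)
        X = np.column_stack([y * 10.0 + rng.normal(0, 0.1, 80),
                             rng.normal(0, 1, 80)])
        plan = train.make_split(y, seed=4)
        best, results = train.grid_search_cv(
            "svm", {"C": [1], "kernel": ["linear"]}, X, y, plan)
        assert results[0]["mean_accuracy"] == 1.0


class TestFcnn:
    def test_space_samples_within_bounds(self):
        space = train.FcnnSpace()
        rng = np.random.default_rng(0)
        for _ in range(50):
            assert space.contains(space.sample(rng))

    def test_memorizes_tiny_dataset(self, rng):
        X = rng.normal(0, 1, (20, 12))
        y = rng.integers(0, 2, 20)
        net = FCNNClassifier(hidden1=64, hidden2=32, dropout1=0.1,
                             dropout2=0.1, learning_rate=1e-2, batch_size=10,
                             max_epochs=200, validation_fraction=0.0,
                             random_state=0)
        net.fit(X, y)
        assert net.loss_curve_[-1] < 0.1

    def test_early_stopping_contract(self):
        """Best loss at epoch 5, patience 3 -> halt after epoch 8."""
        stopper = EarlyStopping(patience=3)
        losses = [0.5, 0.4, 0.3, 0.2, 0.1, 0.2, 0.3, 0.4, 0.5]
        stopped_at = None
        for epoch, loss in enumerate(losses, start=1):
            if stopper.update(loss):
                stopped_at = epoch
                break
        assert stopped_at == 8 and stopper.best_epoch == 4   # 0-based epoch 5

    def test_probabilities_valid_and_deterministic(self, rng):
        X = rng.normal(0, 1, (40, 8))
        y = (X[:, 0] > 0).astype(int)
        net = FCNNClassifier(hidden1=16, hidden2=8, max_epochs=20,
                             validation_fraction=0.0, random_state=1)
        net.fit(X, y)
        P = net.predict_proba(np.vstack([X[:3], X[:3]]))
        assert ((P >= 0) & (P <= 1)).all()
        assert np.allclose(P[:3], P[3:])   # duplicated rows identical
        assert np.array_equal(net.predict(X), (net.predict_proba(X)[:, 1] >= 0.5))

    def test_refit_reproducible_for_fixed_seed(self, rng):
        X = rng.normal(0, 1, (60, 6))
        y = (X.sum(axis=1) > 0).astype(int)
        nets = [FCNNClassifier(hidden1=16, hidden2=8, max_epochs=10,
                               validation_fraction=0.0, random_state=7).fit(X, y)
                for _ in range(2)]
        assert np.array_equal(nets[0].predict_proba(X), nets[1].predict_proba(X))


class TestMultiView:
    def _blocks(self):
        morgan = FingerprintBlock("morgan", np.zeros((3, 2048), np.uint8),
                                  ["a", "b", "c"])
        maccs = FingerprintBlock("maccs", np.ones((3, 166), np.uint8),
                                 ["a", "b", "c"])
        desc = DescriptorBlock(np.arange(6, dtype=float).reshape(3, 2),
                               ["d1", "d2"], ["a", "b", "c"])
        return morgan, maccs, desc

    def test_column_layout_and_provenance(self):
        mv = train.build_multiview(*self._blocks())
        assert mv.values.shape == (3, 2048 + 166 + 2)
        assert (mv.provenance[:2048] == "morgan").all()
        assert (mv.provenance[2048:2214] == "maccs").all()
        assert (mv.provenance[2214:] == "descriptor").all()
        assert mv.names[-2:] == ["d1", "d2"]

    def test_trained_model_width_mismatch_names_layout(self, rng):
        from sklearn.ensemble import RandomForestClassifier
        X = rng.random((20, 5))
        y = rng.integers(0, 2, 20)
        est = RandomForestClassifier(n_estimators=5, random_state=0).fit(X, y)
        model = train.TrainedModel("rf", "descriptors", est, {},
                                   [f"d{i}" for i in range(5)])
        proba, cls = model.predict(X)
        assert ((proba >= 0) & (proba <= 1)).all()
        assert np.array_equal(cls, (proba >= 0.5).astype(int))
        with pytest.raises(ValueError, match="descriptors"):
            model.predict(rng.random((2, 7)))
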