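import numpy as np
import pytest

from llps_pscreen import (
    feature_names,
    fit_behavior_model,
    make_sg10cv_plan,
    predict_behavior,
    roc_auc,
    run_repeated_sg10cv,
    tune_hyperparameters,
)
from llps_pscreen.behavior_model import get_algorithm, standardize


def brute_force_auc(scores, labels):
    """Pair-counting oracle: P(score+ > score-) + 0.5 P(tie)."""
    scores, labels = np.asarray(scores), np.asarray(labels)
    pos, neg = scores[labels == 1], scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestSGCVPlan:
    def test_balanced_toy_instance(self):
        """20 singleton groups, balanced labels: each fold tests one of each class."""
        labels = np.array([0, 1] * 10)
        groups = np.array([f"g{i}" for i in range(20)], dtype=object)
        plan = make_sg10cv_plan(labels, groups, k=10, seed=0)
        for _, test in plan.folds:
            assert len(test) == 2
            assert sorted(labels[test]) == [0, 1]

    def test_no_group_straddles_a_fold(self, behavior_dataset):
        y, groups = behavior_dataset["y"], behavior_dataset["groups"]
        plan = make_sg10cv_plan(y, groups, seed=4)
        for train, test in plan.folds:
            assert not (set(groups[train]) & set(groups[test]))

    def test_folds_partition_the_dataset(self, behavior_dataset):
        y, groups = behavior_dataset["y"], behavior_dataset["groups"]
        plan = make_sg10cv_plan(y, groups, seed=4)
        all_test = np.concatenate([test for _, test in plan.folds])
        assert sorted(all_test) == list(range(len(y)))

    def test_deterministic_given_seed(self, behavior_dataset):
        y, groups = behavior_dataset["y"], behavior_dataset["groups"]
        a = make_sg10cv_plan(y, groups, seed=9)
        b = make_sg10cv_plan(y, groups, seed=9)
        for (ta, sa), (tb, sb) in zip(a.folds, b.folds):
            np.testing.assert_array_equal(ta, tb)
            np.testing.assert_array_equal(sa, sb)

    def test_fewer_groups_than_folds_errors(self):
        with pytest.raises(ValueError, match="groups"):
            make_sg10cv_plan([0, 1, 0], ["a", "a", "b"], k=10)


class TestStandardize:
    def test_hand_z_scores(self):
        scaler, out = standardize(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(out.ravel(), [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_constant_column_passes_through(self):
        scaler, out = standardize(np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]]))
        np.testing.assert_allclose(out[:, 0], 0.0)

    def test_test_rows_never_reach_the_fit(self, rng):
        """Poisoned test rows leave the train transform unchanged."""
        train = rng.standard_normal((50, 3))
        scaler, _ = standardize(train)
        mean_before = scaler.mean_.copy()
        poisoned = np.full((5, 3), 1e9)
        transformed = scaler.transform(poisoned)
        np.testing.assert_array_equal(scaler.mean_, mean_before)
        assert np.all(transformed > 1e6)  # scaled with train stats, not its own

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError):
            standardize(np.empty((0, 3)))


class TestRocAuc:
    def test_perfect_ranking(self):
        assert roc_auc([0.9, 0.8, 0.3, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="one class"):
            roc_auc([0.1, 0.2], [1, 1])

    def test_equals_pair_counting_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 50))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # ties likely
            assert roc_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )


class TestTuning:
    def _interaction_data(self, rng, n=400):
        X = rng.integers(0, 2, size=(n, 2)).astype(float)
        y_xor = (X[:, 0].astype(int) ^ X[:, 1].astype(int)).astype(int)
        y_add = X[:, 0].astype(int)
        return X, y_xor, y_add

    def test_grid_of_one_returned_without_search(self):
        params = tune_hyperparameters(
            np.zeros((4, 2)), [0, 1, 0, 1], "rf", grid={"max_depth": [3]}
        )
        assert params == {"max_depth": 3}

    def test_depth_selection_tracks_rule_structure(self, rng):
        X, y_xor, y_add = self._interaction_data(rng)
        grid = {"max_depth": [1, 3], "n_estimators": [50]}
        deep = tune_hyperparameters(X, y_xor, "rf", grid=grid, seed=0)
        shallow = tune_hyperparameters(X, y_add, "rf", grid=grid, seed=0)
        assert deep["max_depth"] == 3      # stumps cannot express the interaction
        assert shallow["max_depth"] == 1   # additive rule: tie broken to grid order

    def test_deterministic_given_seed(self, behavior_dataset):
        X, y = behavior_dataset["X"][:200], behavior_dataset["y"][:200]
        grid = {"n_estimators": [10, 30]}
        a = tune_hyperparameters(X, y, "adaboost", grid=grid, seed=5)
        b = tune_hyperparameters(X, y, "adaboost", grid=grid, seed=5)
        assert a == b

    def test_unknown_algorithm_errors(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            get_algorithm("deep_dream")


@pytest.fixture(scope="module")
def separable_bundle():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((200, 131))
    y = (X[:, 128] > 0).astype(int)  # ionic-strength column decides
    return fit_behavior_model(X, y, "rf", {"n_estimators": 50}, seed=0), X, y


class TestPredictBehavior:

    def test_training_points_recovered(self, separable_bundle):
        bundle, X, y = separable_bundle
        _, labels = predict_behavior(bundle, X)
        assert (labels == y).mean() == 1.0

    def test_batch_shape_and_range(self, separable_bundle, rng):
        bundle, _, _ = separable_bundle
        proba, labels = predict_behavior(bundle, rng.standard_normal((7, 131)))
        assert proba.shape == labels.shape == (7,)
        assert np.all((proba >= 0) & (proba <= 1))

    def test_row_order_invariance(self, separable_bundle, rng):
        bundle, X, _ = separable_bundle
        batch = X[:10]
        proba, _ = predict_behavior(bundle, batch)
        proba_rev, _ = predict_behavior(bundle, batch[::-1])
        np.testing.assert_allclose(proba, proba_rev[::-1])

    def test_wrong_dimensionality_errors(self, separable_bundle):
        bundle, _, _ = separable_bundle
        with pytest.raises(ValueError, match="131"):
            predict_behavior(bundle, np.zeros((2, 60)))


class TestRepeatedSGCV:
    def test_separable_data_reaches_auc_one(self, rng):
        groups = np.array([f"g{i % 20}" for i in range(300)], dtype=object)
        X = rng.standard_normal((300, 131))
        y = (X[:, 126] > 0).astype(int)
        result = run_repeated_sg10cv(
            X, y, groups, "rf", repeats=1, seed=0, tune=False,
            grid={"n_estimators": [100]},
        )
        assert result.roc.overall_mean_auc > 0.99

    def test_summary_identities(self, behavior_dataset):
        d = behavior_dataset
        result = run_repeated_sg10cv(
            d["X"], d["y"], d["groups"], "adaboost", repeats=2, seed=0, tune=False
        )
        roc = result.roc
        assert roc.overall_mean_auc == pytest.approx(np.mean(roc.repeat_mean_aucs))
        for aucs, mean in zip(roc.fold_aucs, roc.repeat_mean_aucs):
            assert mean == pytest.approx(np.mean(aucs))
        imp = result.importances
        np.testing.assert_allclose(
            imp.grand_mean, np.mean(imp.repeat_means, axis=0)
        )
        assert np.all(imp.grand_mean >= 0)
        assert len(imp.top(10)) == 10
        # standardization is skipped for tree models
        assert all(
            b.scaler is None for rep in result.repeats for b in rep.fold_bundles
        )

    def test_fold_bundles_record_their_training_groups(self, behavior_dataset):
        d = behavior_dataset
        result = run_repeated_sg10cv(
            d["X"], d["y"], d["groups"], "adaboost", repeats=1, seed=1, tune=False
        )
        rep = result.repeats[0]
        for bundle, test_groups in zip(rep.fold_bundles, rep.fold_test_groups):
            assert not (bundle.train_groups & test_groups)


def test_feature_names_registry():
    names = feature_names()
    assert len(names) == 131
    assert len(set(names)) == 131
    assert names[-5:] == [
        "log_protein_conc", "log_rna_conc", "ionic_strength", "pH", "temperature",
    ]
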