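import numpy as np
import pytest
from sklearn.tree import DecisionTreeRegressor

from tfcrkit import ml
from tfcrkit.ml import (
    METHOD_REGISTRY,
    EvalReport,
    ModelSpec,
    attribute,
    build_pooled_training_set,
    cross_validate,
    encode_features,
    enumerate_training_tasks,
    evaluate,
    feature_names,
    importance_by_permutation,
    onehot_sequence,
    split_dataset,
    train_regressor,
)


class TestEncoding:
    def test_acgt_identity_pattern(self):
        m = onehot_sequence("ACGT", 6)
        assert m.shape == (4, 6)
        np.testing.assert_array_equal(m[:, :4], np.eye(4))
        np.testing.assert_array_equal(m[:, 4:], 0)

    def test_n_is_all_zero(self):
        m = onehot_sequence("ANA", 3)
        np.testing.assert_array_equal(m[:, 1], 0)
        assert m[:, 0].sum() == 1 and m[:, 2].sum() == 1

    def test_two_kb_promoter_is_4000_positions(self):
        seq = "A" * 4000  # a +/-2kb promoter window
        fv = encode_features(seq, "ACGT", distance=0.0)
        assert fv.promoter_onehot.shape == (4, 4000)
        assert fv.tfcr_onehot.shape == (4, ml.DEFAULT_L_TFCR)

    def test_too_long_errors(self):
        with pytest.raises(ValueError):
            onehot_sequence("ACGTA", 4)

    def test_flatten_layout(self):
        fv = encode_features("AC", "G", 7.0, l_promoter=2, l_tfcr=2)
        flat = fv.flatten()
        names = feature_names(2, 2)
        assert len(flat) == len(names) == 4 * 2 + 4 * 2 + 1
        assert names[-1] == "distance"
        assert flat[-1] == 7.0
        assert flat[names.index("prom_0_A")] == 1.0
        assert flat[names.index("prom_1_C")] == 1.0
        assert flat[names.index("tfcr_0_G")] == 1.0

    def test_one_hot_column_sums(self, rng):
        seq = "".join(rng.choice(list("ACGTN"), size=50))
        m = onehot_sequence(seq, 80)
        sums = m.sum(axis=0)
        for i, base in enumerate(seq):
            assert sums[i] == (0 if base == "N" else 1)
        np.testing.assert_array_equal(sums[50:], 0)


class TestSplit:
    def test_eighty_twenty(self):
        train, test = split_dataset(list(range(100)), seed=0)
        assert len(train) == 80 and len(test) == 20

    def test_seed_reproducible(self):
        a = split_dataset(list(range(50)), seed=3)
        b = split_dataset(list(range(50)), seed=3)
        assert a == b

    def test_union_is_input(self):
        train, test = split_dataset(list(range(37)), seed=1)
        assert sorted(train + test) == list(range(37))

    def test_too_few_errors(self):
        with pytest.raises(ValueError):
            split_dataset(list(range(9)))


class TestPooledTrainingSet:
    def test_six_species_180k(self):
        sets = {
            f"sp{i}": [list(range(40)) for _ in range(n_stages)]
            for i, n_stages in enumerate([1, 2, 3, 5, 7, 14])
        }
        pooled = build_pooled_training_set(sets, seed=0)
        assert len(pooled) == 180_000
        counts = {}
        for species, _, _ in pooled:
            counts[species] = counts.get(species, 0) + 1
        assert all(c == 30_000 for c in counts.values())

    def test_three_stages_10k_each(self):
        pooled = build_pooled_training_set({"sp": [list(range(5))] * 3}, seed=0)
        stage_counts = {}
        for _, stage, _ in pooled:
            stage_counts[stage] = stage_counts.get(stage, 0) + 1
        assert stage_counts == {0: 10_000, 1: 10_000, 2: 10_000}

    def test_single_stage_with_replacement(self):
        pooled = build_pooled_training_set({"sp": [[1, 2, 3]]}, seed=0)
        assert len(pooled) == 30_000

    def test_remainder_goes_to_first_stage(self):
        pooled = build_pooled_training_set({"sp": [list(range(3))] * 7}, seed=0)
        stage_counts = {}
        for _, stage, _ in pooled:
            stage_counts[stage] = stage_counts.get(stage, 0) + 1
        assert stage_counts[0] == 30_000 // 7 + 30_000 % 7
        assert sum(stage_counts.values()) == 30_000

    def test_empty_stage_errors(self):
        with pytest.raises(ValueError):
            build_pooled_training_set({"sp": []})


class TestRegistry:
    def test_eleven_methods(self):
        assert len(METHOD_REGISTRY) == 11

    def test_enumerate_407_tasks(self):
        tasks = enumerate_training_tasks(
            sorted(METHOD_REGISTRY), [f"ds{i}" for i in range(37)]
        )
        assert len(tasks) == 407

    def test_unknown_method_errors(self):
        with pytest.raises(ValueError):
            ModelSpec("catboost2")
        with pytest.raises(ValueError):
            enumerate_training_tasks(["nope"], ["d"])

    def test_all_methods_fit_predict(self, rng):
        X = rng.random((60, 5))
        y = X[:, 0] + 0.1 * rng.standard_normal(60)
        for method in METHOD_REGISTRY:
            spec = ModelSpec(method, seed=1)
            if method in ("gb_trees",):
                spec.hyperparams = {"iterations": 20, "depth": 2}
            model = train_regressor(spec, X, y)
            pred = model.predict(X)
            assert pred.shape == (60,)
            assert np.isfinite(pred).all()

    def test_tree_methods_deterministic(self, rng):
        X = rng.random((80, 6))
        y = X[:, 1] * 2 + rng.standard_normal(80) * 0.1
        for method in ("dtree", "rforest", "gbdt"):
            a = train_regressor(ModelSpec(method, seed=5), X, y).predict(X)
            b = train_regressor(ModelSpec(method, seed=5), X, y).predict(X)
            np.testing.assert_array_equal(a, b)


class TestTrainEvaluate:
    def test_constant_target(self, rng):
        X = rng.random((40, 3))
        y = np.full(40, 2.5)
        model = train_regressor(ModelSpec("dtree", seed=0), X, y)
        with pytest.warns(UserWarning):
            report = evaluate(model, X, y)
        assert report.rmse == pytest.approx(0.0)
        assert np.isnan(report.pearson_r)

    def test_linear_distance_signal_r2(self, rng):
        # target linear in a distance column among noise features
        X = rng.random((5000, 10))
        y = 3.0 * X[:, -1]
        spec = ModelSpec("gb_trees", {"iterations": 100, "depth": 3}, seed=0)
        model = train_regressor(spec, X[:4000], y[:4000])
        report = evaluate(model, X[4000:], y[4000:])
        assert report.r_squared > 0.9

    def test_perfect_predictions(self):
        class Identity:
            def predict(self, X):
                return X[:, 0]

        X = np.arange(10.0)[:, None]
        report = evaluate(Identity(), X, X[:, 0])
        assert report.pearson_r == pytest.approx(1.0)
        assert report.spearman_R == pytest.approx(1.0)
        assert report.r_squared == pytest.approx(1.0)
        assert report.mae == 0.0 and report.rmse == 0.0

    def test_shifted_predictions(self):
        class Shifted:
            def predict(self, X):
                return X[:, 0] + 1.0

        X = np.arange(10.0)[:, None]
        report = evaluate(Shifted(), X, X[:, 0])
        assert report.pearson_r == pytest.approx(1.0)
        assert report.mae == pytest.approx(1.0)

    def test_random_vs_random_small_r(self, rng):
        class Noise:
            def __init__(self, rng):
                self.rng = rng

            def predict(self, X):
                return self.rng.random(len(X))

        report = evaluate(Noise(np.random.default_rng(0)), np.zeros((1000, 1)),
                          np.random.default_rng(1).random(1000))
        assert abs(report.pearson_r) < 0.1

    def test_cross_validate_returns_k_reports(self, rng):
        X = rng.random((50, 4))
        y = X[:, 0]
        reports = cross_validate(ModelSpec("knn"), X, y, k=5)
        assert len(reports) == 5
        assert all(isinstance(r, EvalReport) for r in reports)


class TestAttribution:
    def test_constant_tree_all_zero(self):
        X = np.zeros((20, 3))
        y = np.full(20, 1.5)
        tree = DecisionTreeRegressor(max_depth=1).fit(X, y)
        report = attribute(tree, X)
        np.testing.assert_allclose(report.values, 0.0, atol=1e-12)
        np.testing.assert_allclose(report.base_values, 1.5)

    def test_stump_on_distance_gets_everything(self, rng):
        X = rng.random((200, 4))
        y = (X[:, 3] > 0.5).astype(float)
        stump = DecisionTreeRegressor(max_depth=1, random_state=0).fit(X, y)
        report = attribute(stump, X, ["a", "b", "c", "distance"])
        imp = report.mean_abs_importance
        assert imp[3] > 0
        np.testing.assert_allclose(imp[:3], 0.0, atol=1e-12)
        assert report.ranking()[0][0] == "distance"

    def test_local_accuracy_gb(self, rng):
        X = rng.random((300, 6))
        y = X[:, 0] * 2 + np.sin(3 * X[:, 1]) + 0.1 * rng.standard_normal(300)
        spec = ModelSpec("gb_trees", {"iterations": 40, "depth": 3}, seed=0)
        model = train_regressor(spec, X, y)
        report = attribute(model, X[:50])
        recon = report.base_values + report.values.sum(axis=1)
        np.testing.assert_allclose(recon, model.predict(X[:50]), atol=1e-6)

    def test_non_tree_model_errors(self, rng):
        X = rng.random((30, 3))
        model = train_regressor(ModelSpec("knn"), X, X[:, 0])
        with pytest.raises(TypeError):
            attribute(model, X)

    def test_distance_dominates_on_synthetic(self):
        from tfcrkit.synthetic import make_regression_dataset

        data = make_regression_dataset(1500, 50, 100, 0.9, seed=0)
        X, y = ml.encode_matrix(data, 50, 100)
        spec = ModelSpec("gb_trees", {"iterations": 40, "depth": 3, "max_features": 64},
                         seed=0)
        model = train_regressor(spec, X, y)
        report = attribute(model, X[:300], feature_names(50, 100))
        assert report.ranking()[0][0] == "distance"


class TestPermutationImportance:
    def _model_and_data(self, rng):
        X = rng.random((400, 5))
        X[:, 2] = 0.0  # constant, irrelevant
        y = 2.0 * X[:, 4] + 0.05 * rng.standard_normal(400)
        model = train_regressor(
            ModelSpec("gb_trees", {"iterations": 50, "depth": 2}, seed=0), X, y
        )
        return model, X, y

    def test_constant_feature_no_change(self, rng):
        model, X, y = self._model_and_data(rng)
        imp = importance_by_permutation(model, X, y, n_repeats=3, seed=0)
        assert abs(imp[2]) < 1e-12

    def test_informative_feature_largest(self, rng):
        model, X, y = self._model_and_data(rng)
        imp = importance_by_permutation(model, X, y, n_repeats=3, seed=0)
        assert np.argmax(imp) == 4

    def test_deterministic(self, rng):
        model, X, y = self._model_and_data(rng)
        a = importance_by_permutation(model, X, y, n_repeats=2, seed=9)
        b = importance_by_permutation(model, X, y, n_repeats=2, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_zero_repeats_errors(self, rng):
        model, X, y = self._model_and_data(rng)
        with pytest.raises(ValueError):
            importance_by_permutation(model, X, y, n_repeats=0)
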