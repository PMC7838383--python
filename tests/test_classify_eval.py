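import numpy as np
import pandas as pd
import pytest

from neuropref.classify_eval import (
    CLASSIFIERS,
    ClassifierSpec,
    FeatureMatrix,
    build_dnn_spec,
    build_feature_matrix,
    evaluate_predictions,
    grid_to_frame,
    holdout_split,
    minmax_normalize,
    run_experiment_grid,
    train_classifier,
)
from neuropref.core_io import RunConfig, SchemaError, ShapeError, ValidationError


def _separable_matrix(n=200, n_features=8, n_informative=2, seed=0):
    """Linearly separable set: informative features shifted by class."""
    rng = np.random.default_rng(seed)
    y = np.array(["like", "dislike"] * (n // 2))
    X = rng.normal(0, 0.5, size=(n, n_features))
    for j in range(n_informative):
        sign = 1.0 if j % 2 == 0 else -1.0
        X[:, j] += sign * np.where(y == "like", 2.0, -2.0)
    cols = [f"f{i}" for i in range(n_features)]
    return FeatureMatrix(pd.DataFrame(X, columns=cols), y)


class TestMinMax:
    def test_train_endpoints(self):
        tr, _, _ = minmax_normalize(np.array([[2.0], [4.0]]))
        assert list(tr[:, 0]) == [0.0, 1.0]

    def test_test_value_uses_train_range(self):
        _, te, _ = minmax_normalize(np.array([[2.0], [4.0]]),
                                    np.array([[3.0], [5.0]]))
        assert te[0, 0] == 0.5
        assert te[1, 0] == 1.5  # may exit [0, 1]

    def test_constant_column_maps_to_zero(self):
        tr, te, _ = minmax_normalize(np.array([[7.0], [7.0]]),
                                     np.array([[7.0]]))
        assert not tr.any() and not te.any()

    def test_empty_train_rejected(self):
        with pytest.raises(ValidationError):
            minmax_normalize(np.empty((0, 3)))


class TestHoldout:
    def test_split_sizes(self):
        m = _separable_matrix(n=100)
        train, test = holdout_split(m, 0.2, seed=0)
        assert len(test) == 20 and len(train) == 80

    def test_deterministic_per_seed(self):
        m = _separable_matrix(n=100)
        a = holdout_split(m, 0.2, seed=5)[1].X
        b = holdout_split(m, 0.2, seed=5)[1].X
        pd.testing.assert_frame_equal(a, b)

    def test_stratification_balance(self):
        m = _separable_matrix(n=200)
        _, test = holdout_split(m, 0.2, seed=1)
        frac = np.mean(test.y == "like")
        assert abs(frac - 0.5) <= 0.05

    def test_single_class_rejected(self):
        m = _separable_matrix(n=50)
        m.y[:] = "like"
        with pytest.raises(ValidationError):
            holdout_split(m, 0.2, seed=0)


class TestDnnSpec:
    def test_published_input_width(self):
        spec = build_dnn_spec(2367, "binary_ce")
        assert spec["hidden"] == (1183, 591, 295)
        assert spec["output"] == 2

    def test_halving_rule(self):
        assert build_dnn_spec(840, "categorical_ce")["hidden"] == (420, 210, 105)

    def test_hinge_head_is_single_margin_unit(self):
        spec = build_dnn_spec(64, "hinge")
        assert spec["output"] == 1 and spec["head"] == "linear_margin"

    def test_tiny_input_rejected(self):
        with pytest.raises(ValueError):
            build_dnn_spec(4, "binary_ce")


class TestTrainClassifier:
    @pytest.mark.parametrize("algo", CLASSIFIERS)
    def test_learns_separable_problem(self, algo):
        # width and sample count in the regime the feature pipeline yields
        # (the halving rule leaves the network too narrow below ~64 inputs)
        m = _separable_matrix(n=800, n_features=64, n_informative=16, seed=2)
        spec = ClassifierSpec(algo, rf_trees=100, seed=2)
        model = train_classifier(spec, m)
        acc = np.mean(model.predict(m.X) == m.y)
        assert acc >= 0.95

    def test_single_class_training_rejected(self):
        m = _separable_matrix(n=40)
        m.y[:] = "dislike"
        with pytest.raises(ValidationError):
            train_classifier(ClassifierSpec("rf", rf_trees=10), m)

    def test_schema_mismatch_at_predict(self):
        m = _separable_matrix(n=60)
        model = train_classifier(ClassifierSpec("knn"), m)
        bad = m.X.rename(columns={"f0": "g0"})
        with pytest.raises(SchemaError):
            model.predict(bad)

    def test_rf_deterministic_per_seed(self):
        m = _separable_matrix(n=100, seed=4)
        p1 = train_classifier(ClassifierSpec("rf", rf_trees=50, seed=9), m).predict(m.X)
        p2 = train_classifier(ClassifierSpec("rf", rf_trees=50, seed=9), m).predict(m.X)
        np.testing.assert_array_equal(p1, p2)

    def test_dnn_deterministic_per_seed(self):
        m = _separable_matrix(n=100, seed=4)
        spec = ClassifierSpec("dnn_binary_ce", dnn_epochs=15, seed=9)
        p1 = train_classifier(spec, m).predict(m.X)
        p2 = train_classifier(spec, m).predict(m.X)
        np.testing.assert_array_equal(p1, p2)


class TestEvaluate:
    def test_perfect_predictions(self):
        r = evaluate_predictions(["like", "dislike"], ["like", "dislike"])
        assert r.accuracy == r.precision == r.recall == 1.0

    def test_hand_computed_confusion(self):
        truth = ["like", "like", "dislike", "dislike"]
        pred = ["like", "dislike", "dislike", "dislike"]
        r = evaluate_predictions(truth, pred)
        assert r.accuracy == 0.75
        assert r.per_class["like"]["precision"] == 1.0
        assert r.per_class["like"]["recall"] == 0.5
        assert r.confusion.sum() == 4

    def test_constant_prediction_on_balanced_truth(self):
        r = evaluate_predictions(["like", "dislike"] * 10, ["like"] * 20)
        assert r.accuracy == 0.5

    def test_length_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            evaluate_predictions(["like"], ["like", "dislike"])

    def test_weighted_recall_equals_accuracy(self, rng):
        """Support-weighted recall coincides with accuracy, always."""
        for _ in range(100):
            n = rng.integers(2, 60)
            truth = rng.choice(["like", "dislike"], size=n)
            pred = rng.choice(["like", "dislike"], size=n)
            r = evaluate_predictions(truth, pred)
            assert r.recall == pytest.approx(r.accuracy, abs=1e-12)


class TestGrid:
    def test_grid_shape_and_report_frame(self, small_synth, run_config):
        epochs, _, _ = small_synth
        cfg = RunConfig()
        cfg.classifiers.rf_trees = 50
        reports = run_experiment_grid(
            epochs, cfg, families=("psd",), classifiers=("rf", "knn"))
        assert len(reports) == 1 * 3 * 2
        frame = grid_to_frame(reports)
        assert len(frame) == 6 * 3  # cells x metrics
        assert set(frame["metric"]) == {"accuracy", "recall", "precision"}

    def test_feature_matrix_widths(self, small_synth):
        epochs, _, _ = small_synth
        cfg = RunConfig()
        assert build_feature_matrix(epochs, "psd", "no_indices", cfg).X.shape[1] == 56
        assert build_feature_matrix(epochs, "psd", "valence_only", cfg).X.shape[1] == 57
        assert build_feature_matrix(epochs, "psd", "all_indices", cfg).X.shape[1] == 64
        assert build_feature_matrix(epochs, "dwt", "all_indices", cfg).X.shape[1] == 848

    def test_unknown_feature_set_rejected(self, small_synth):
        with pytest.raises(ValidationError):
            build_feature_matrix(small_synth[0], "psd", "bogus")
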