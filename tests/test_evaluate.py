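"""Classifier training, reported metrics, and the CV experiment loop."""

import numpy as np
import pandas as pd
import pytest

from oracles import kappa_oracle
from somnoboost import (
    CVReport,
    ExperimentConfig,
    cohen_kappa,
    cv_mean,
    fold_metrics,
    multiclass_logloss,
    run_experiment,
    train,
)


@pytest.fixture(scope="module")
def separable_toy(rng=np.random.default_rng(77)):
    """500 rows, 2 features, 5 linearly separable classes."""
    y = rng.integers(0, 5, 500)
    X = np.column_stack([y * 10.0, -y * 5.0]) + rng.normal(0, 0.5, (500, 2))
    return X, y


class TestTrain:
    def test_separable_toy_high_accuracy(self, separable_toy):
        X, y = separable_toy
        model = train(X, y, seed=0)
        assert np.mean(model.predict(X) == y) >= 0.99

    def test_deterministic(self, separable_toy):
        X, y = separable_toy
        a = train(X, y, seed=3).predict_proba(X)
        b = train(X, y, seed=3).predict_proba(X)
        np.testing.assert_array_equal(a, b)

    def test_param_validation_before_training(self, separable_toy):
        X, y = separable_toy
        with pytest.raises(ValueError, match="learning_rate"):
            train(X, y, {"learning_rate": 2.0})
        with pytest.raises(ValueError, match="booster"):
            train(X, y, {"booster": "gblinear"})

    def test_label_and_nan_checks(self, separable_toy):
        X, y = separable_toy
        with pytest.raises(ValueError, match="labels"):
            train(X, y + 3)
        X_bad = X.copy()
        X_bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            train(X_bad, y)


class TestMulticlassLogloss:
    def test_perfect_predictions_near_zero(self):
        y = np.array([0, 1, 2, 3, 4])
        proba = np.eye(5)[y]
        assert multiclass_logloss(y, proba) < 1e-10

    def test_uniform_is_log5(self, rng):
        y = rng.integers(0, 5, 40)
        proba = np.full((40, 5), 0.2)
        assert multiclass_logloss(y, proba) == pytest.approx(np.log(5))

    def test_half_probability_is_log2(self):
        proba = np.array([[0.5, 0.5, 0, 0, 0]])
        assert multiclass_logloss(np.array([0]), proba) == pytest.approx(np.log(2))

    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            multiclass_logloss(np.array([0]), np.array([[0.5, 0.1, 0, 0, 0]]))


class TestCohenKappa:
    def test_perfect_agreement(self):
        y = np.array([0, 1, 2, 3, 4, 0, 1])
        assert cohen_kappa(y, y) == 1.0

    def test_chance_level_symmetry(self):
        assert cohen_kappa(np.array([0, 0, 1, 1]), np.array([0, 1, 0, 1])) == 0.0

    def test_hand_contingency_case(self):
        t, p = np.array([0, 0, 0, 1]), np.array([0, 0, 1, 1])
        # Po=0.75; marginals 3/1 vs 2/2 → Pe=(3·2+1·2)/16=0.5 → κ=0.5
        assert cohen_kappa(t, p) == pytest.approx(0.5)

    def test_matches_oracle_and_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score

        for _ in range(30):
            t = rng.integers(0, 5, 60)
            p = rng.integers(0, 5, 60)
            k = cohen_kappa(t, p)
            assert k == pytest.approx(kappa_oracle(list(t), list(p)), rel=1e-10)
            assert k == pytest.approx(cohen_kappa_score(t, p), rel=1e-10)

    def test_both_constant_equal(self):
        with pytest.warns(UserWarning, match="constant"):
            assert cohen_kappa(np.zeros(5, int), np.zeros(5, int)) == 1.0


class TestFoldMetrics:
    def test_perfect_predictions(self):
        y = np.tile(np.arange(5), 4)
        proba = np.eye(5)[y]
        fr = fold_metrics(y, y, proba)
        assert fr.accuracy == fr.f1 == fr.precision == fr.recall == fr.kappa == 1.0
        conf = np.array(fr.confusion)
        assert np.all(conf == np.diag([4] * 5))

    def test_constant_prediction_on_balanced_truth(self):
        y = np.tile(np.arange(5), 4)
        pred = np.zeros_like(y)
        proba = np.eye(5)[pred]
        fr = fold_metrics(y, pred, proba)
        assert fr.accuracy == pytest.approx(0.2)
        assert fr.kappa == pytest.approx(0.0)

    def test_fixed_case_matches_hand_computation(self):
        y = np.array([0] * 8 + [1] * 6 + [2] * 6)
        pred = np.array([0] * 6 + [1] * 2 + [1] * 5 + [0] * 1 + [2] * 4 + [1] * 2)
        proba = np.eye(5)[pred]
        with pytest.warns(UserWarning):
            fr = fold_metrics(y, pred, proba)
        assert fr.accuracy == pytest.approx(15 / 20)
        # weighted recall equals accuracy by definition
        assert fr.recall == pytest.approx(15 / 20)
        # per-class precision: 0→6/7, 1→5/9, 2→4/4; weights 8,6,6 of 20
        expected_precision = (8 * 6 / 7 + 6 * 5 / 9 + 6 * 1.0) / 20
        assert fr.precision == pytest.approx(expected_precision)
        assert fr.kappa == pytest.approx(kappa_oracle(list(y), list(pred)))

    def test_accuracy_equals_confusion_trace(self, rng):
        y = rng.integers(0, 5, 100)
        pred = rng.integers(0, 5, 100)
        fr = fold_metrics(y, pred, np.eye(5)[pred])
        conf = np.array(fr.confusion)
        assert fr.accuracy == pytest.approx(np.trace(conf) / conf.sum())


class TestCVMean:
    def test_rounded_mean_reported(self):
        full, rounded = cv_mean([0.8449, 0.8451])
        assert full == pytest.approx(0.845)
        assert rounded == 0.845

    def test_constant_list(self):
        assert cv_mean([0.7] * 10) == (pytest.approx(0.7), 0.7)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cv_mean([])


def _toy_matrix(n_per_class=30, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat(np.arange(5), n_per_class)
    X = rng.normal(0, 0.4, (y.size, 3)) + y[:, None]
    df = pd.DataFrame(X, columns=["f0", "f1", "f2"])
    df["age"] = 30.0
    df["recording_id"] = "r"
    df["epoch"] = range(y.size)
    df["stage"] = y
    return df


class TestRunExperiment:
    def test_mean_row_is_cv_mean_of_folds(self):
        rep = run_experiment(_toy_matrix(), mode="default", seed=0)
        for metric in ("accuracy", "kappa", "f1"):
            values = [getattr(f, metric) for f in rep.folds]
            assert rep.mean[metric] == pytest.approx(cv_mean(values)[0])

    def test_report_round_trip_and_table(self, tmp_path):
        rep = run_experiment(
            _toy_matrix(), mode="default",
            config=ExperimentConfig(k=5, capture_curves=True), seed=1,
        )
        path = tmp_path / "report.json"
        rep.to_json(path)
        assert path.exists() and path.read_text().startswith("{")
        table = rep.metrics_table()
        assert list(table.columns) == [
            "Fold", "Accuracy", "F1-Score", "Precision", "Recall", "Kappa",
        ]
        assert table.iloc[-1]["Fold"] == "Mean"
        assert len(rep.folds[0].train_logloss_curve) > 0
        assert len(rep.folds[0].test_error_curve) > 0

    def test_reproducible_given_seed(self):
        a = run_experiment(_toy_matrix(), mode="default", seed=3)
        b = run_experiment(_toy_matrix(), mode="default", seed=3)
        assert a.to_json() == b.to_json()

    def test_balancing_never_sees_test_rows(self, monkeypatch):
        """Leakage guard: every row given to the balancer is a training row."""
        import somnoboost.evaluate as ev

        data = _toy_matrix(n_per_class=25, seed=5)
        # make class 4 scarce so balancing has real work to do
        data = data[~((data["stage"] == 4) & (data["epoch"] % 3 == 0))]
        seen = []
        original = ev.balance_training

        def recording_balance(rows, labels, seed=0):
            seen.append(np.asarray(rows))
            return original(rows, labels, seed)

        monkeypatch.setattr(ev, "balance_training", recording_balance)
        cols = ["f0", "f1", "f2", "age"]
        X = data[cols].to_numpy()
        rep = run_experiment(data, mode="default",
                             config=ExperimentConfig(k=5), seed=7)
        assert len(seen) == 5
        all_rows = {tuple(r) for r in X}
        for batch in seen:
            # balancer input is a strict subset of the dataset's rows
            assert all(tuple(r) in all_rows for r in batch)
        # across the 5 folds each row appears in exactly 4 training sets
        from collections import Counter

        counts = Counter(tuple(r) for batch in seen for r in set(map(tuple, batch)))
        assert all(c == 4 for c in counts.values())

    def test_invalid_mode(self):
        with pytest.raises(ValueError, match="mode"):
            run_experiment(_toy_matrix(), mode="grid")
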