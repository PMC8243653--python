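import numpy as np
import pandas as pd
import pytest

from pacdetect.model import (
    CVResult,
    FoldPlan,
    RFConfig,
    cap_training,
    confusion_counts,
    cross_validate,
    derive_seed,
    feature_importance,
    make_folds,
    metrics_from_confusion,
    patientwise_metrics,
    row_normalized_percent,
    train_rf,
)


class TestFolds:
    def test_equal_s_one_per_fold(self):
        s = {f"p{i}": 10 for i in range(10)}
        plan = make_folds(s, k=10, seed=1)
        assert sorted(plan.assignment.values()) == list(range(10))

    def test_partition_property(self):
        rng = np.random.default_rng(2)
        s = {f"p{i}": int(rng.integers(0, 500)) for i in range(37)}
        plan = make_folds(s, k=10, seed=3)
        assert set(plan.assignment) == set(s)
        folds = [plan.patients_in_fold(f) for f in range(10)]
        union = [p for fold in folds for p in fold]
        assert sorted(union) == sorted(s)  # disjoint cover

    def test_patient_atomicity(self):
        s = {"big": 100}
        s.update({f"p{i}": 0 for i in range(19)})
        plan = make_folds(s, k=10, seed=4)
        heavy = plan.assignment["big"]
        assert plan.fold_s_counts[heavy] == 100
        assert sum(plan.fold_s_counts) == 100

    def test_too_few_patients(self):
        with pytest.raises(ValueError):
            make_folds({"a": 1, "b": 2}, k=10)

    def test_deterministic(self):
        s = {f"p{i}": i % 5 for i in range(25)}
        assert make_folds(s, seed=7).assignment == make_folds(s, seed=7).assignment

    def test_balance_spread(self):
        rng = np.random.default_rng(8)
        s = {f"p{i}": int(rng.integers(50, 150)) for i in range(60)}
        plan = make_folds(s, k=10, seed=8)
        assert plan.relative_s_spread() <= 0.20


class TestCap:
    def _frame(self, n_n, n_s, n_v):
        labels = ["N"] * n_n + ["S"] * n_s + ["V"] * n_v
        return pd.DataFrame({"label": labels, "x": np.arange(len(labels))})

    def test_cap_applied(self):
        out = cap_training(self._frame(30000, 2000, 1500), cap=10000, seed=1)
        counts = out["label"].value_counts()
        assert counts["N"] == 10000 and counts["S"] == 2000 and counts["V"] == 1500

    def test_identity_below_cap(self):
        df = self._frame(100, 50, 25)
        out = cap_training(df, cap=10000, seed=1)
        pd.testing.assert_frame_equal(out, df)

    def test_deterministic(self):
        df = self._frame(500, 10, 10)
        a = cap_training(df, cap=100, seed=5)
        b = cap_training(df, cap=100, seed=5)
        pd.testing.assert_frame_equal(a, b)
        c = cap_training(df, cap=100, seed=6)
        assert not a.equals(c)


class TestTrainRF:
    def test_degenerate_labels(self):
        X = np.random.default_rng(0).normal(size=(50, 3))
        with pytest.raises(ValueError, match="single class"):
            train_rf(X, ["N"] * 50)

    def test_separable_data(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.1, (40, 2)), rng.normal(5, 0.1, (40, 2))])
        y = ["N"] * 40 + ["S"] * 40
        clf = train_rf(X, y, RFConfig(n_estimators=50, seed=0))
        assert (clf.predict(X) == np.asarray(y)).mean() == 1.0

    def test_binary_mode_relabels(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 3))
        y = ["N"] * 20 + ["S"] * 20 + ["V"] * 20
        clf = train_rf(X, y, RFConfig(n_estimators=20, seed=0), mode="binary")
        assert set(clf.classes_) == {"S", "O"}

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(80, 4))
        y = list(rng.choice(["N", "S"], 80))
        p1 = train_rf(X, y, RFConfig(n_estimators=30, seed=9)).predict(X)
        p2 = train_rf(X, y, RFConfig(n_estimators=30, seed=9)).predict(X)
        assert (p1 == p2).all()


class TestMetrics:
    # hand-built confusion: rows sum to 100 each
    CM = np.array([[90, 6, 4], [12, 80, 8], [20, 10, 70]])

    def test_oracle_arithmetic(self):
        m = metrics_from_confusion(self.CM, ("N", "S", "V"))
        # class N: TP=90 FN=10 FP=32 TN=168
        assert m["N"]["sensitivity"] == pytest.approx(100 * 90 / 100)
        assert m["N"]["specificity"] == pytest.approx(100 * 168 / 200)
        assert m["N"]["ppv"] == pytest.approx(100 * 90 / 122)
        assert m["N"]["npv"] == pytest.approx(100 * 168 / 178)
        assert m["N"]["accuracy"] == pytest.approx(100 * 258 / 300)
        # class S: TP=80 FN=20 FP=16 TN=184
        assert m["S"]["sensitivity"] == pytest.approx(80.0)
        assert m["S"]["ppv"] == pytest.approx(100 * 80 / 96)
        # class V: TP=70 FN=30 FP=12 TN=188
        assert m["V"]["specificity"] == pytest.approx(100 * 188 / 200)

    def test_rows_sum_100(self):
        pct = row_normalized_percent(self.CM)
        assert np.allclose(pct.sum(axis=1), 100.0, atol=1e-6)

    def test_confusion_counts(self):
        cm = confusion_counts(["N", "S", "N"], ["N", "N", "S"], ("N", "S"))
        assert cm.tolist() == [[1, 1], [1, 0]]

    def test_patientwise_excludes_absent_class(self):
        preds = pd.DataFrame(
            {
                "patient_id": ["a"] * 4 + ["b"] * 4,
                "y_true": ["N", "N", "S", "S", "N", "N", "N", "N"],
                "y_pred": ["N", "N", "S", "N", "N", "N", "N", "S"],
            }
        )
        summary = patientwise_metrics(preds, ("N", "S"))
        assert summary["S"]["n_patients"] == 1  # patient b has no true S
        assert summary["N"]["n_patients"] == 2
        assert summary["S"]["sensitivity"]["median"] == pytest.approx(50.0)


def _synthetic_dataset(n_patients=12, beats_per_patient=60, seed=0):
    """Separable 3-class feature table with patient structure."""
    rng = np.random.default_rng(seed)
    rows = []
    centers = {"N": 0.0, "S": 3.0, "V": -3.0}
    for p in range(n_patients):
        labels = rng.choice(["N", "S", "V"], size=beats_per_patient, p=[0.7, 0.2, 0.1])
        for j, lab in enumerate(labels):
            rows.append(
                {
                    "patient_id": f"p{p:02d}",
                    "beat_sample": j * 200,
                    "label": lab,
                    "f1": centers[lab] + rng.normal(0, 0.4),
                    "f2": rng.normal(0, 1.0),
                    "f3": centers[lab] * 0.5 + rng.normal(0, 0.6),
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def result():
    df = _synthetic_dataset()
    plan = make_folds(
        df.groupby("patient_id")["label"].apply(lambda s: (s == "S").sum()).to_dict(),
        k=3,
        seed=1,
    )
    cfg = RFConfig(n_estimators=40, seed=2)
    return df, cross_validate(df, plan, cfg, mode="multiclass")


class TestCrossValidate:
    def test_no_patient_leak(self, result):
        _, res = result
        for entry in res.audit:
            assert not set(entry["train_patients"]) & set(entry["test_patients"])

    def test_every_beat_predicted_once(self, result):
        df, res = result
        assert len(res.predictions) == len(df)
        keys = res.predictions[["patient_id", "beat_sample"]].apply(tuple, axis=1)
        assert keys.is_unique

    def test_pooled_equals_summed_per_fold(self, result):
        _, res = result
        assert (res.confusion == sum(res.per_fold_confusions)).all()

    def test_separable_accuracy(self, result):
        _, res = result
        correct = (res.predictions["y_true"] == res.predictions["y_pred"]).mean()
        assert correct > 0.9

    def test_binary_mode(self):
        df = _synthetic_dataset(seed=3)
        plan = make_folds(
            df.groupby("patient_id")["label"].apply(lambda s: (s == "S").sum()).to_dict(),
            k=2, seed=1,
        )
        res = cross_validate(df, plan, RFConfig(n_estimators=30, seed=4), mode="binary")
        assert set(res.predictions["y_true"]) <= {"S", "O"}
        assert res.classes == ("S", "O")


class TestImportance:
    def test_informative_feature_first(self):
        rng = np.random.default_rng(10)
        n = 400
        y = rng.choice(["N", "S"], size=n)
        signal = np.where(y == "S", 2.0, -2.0) + rng.normal(0, 0.3, n)
        X = np.column_stack([rng.normal(size=n), signal, rng.normal(size=n)])
        clf = train_rf(X, y, RFConfig(n_estimators=60, seed=0))
        series = pd.Series(clf.feature_importances_, index=["noise1", "signal", "noise2"],
                           name="fold0")
        top = feature_importance([series], top=3)
        assert top.iloc[0]["feature"] == "signal"
        assert clf.feature_importances_.sum() == pytest.approx(1.0, abs=1e-9)

    def test_ten_rows_per_fold(self):
        rng = np.random.default_rng(11)
        series = pd.Series(rng.random(30), index=[f"f{i}" for i in range(30)], name="fold0")
        out = feature_importance([series], top=10)
        assert len(out) == 10
        assert list(out["rank"]) == list(range(1, 11))


def test_derive_seed_stable():
    assert derive_seed(1, "a") == derive_seed(1, "a")
    assert derive_seed(1, "a") != derive_seed(1, "b")
    assert derive_seed(2, "a") != derive_seed(1, "a")
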