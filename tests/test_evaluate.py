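"""Metric arithmetic, cross-validation protocols, correlations, hypnograms."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import BaseEstimator, ClassifierMixin

from remstage.errors import ConfigError, DataError
from remstage.evaluate import (
    crossval,
    feature_target_correlation,
    hypnogram_compare,
    per_class_metrics,
)
from remstage.features import FeatureMatrix
from remstage.models import ModelSpec
from remstage.types import Hypnogram


class TestPerClassMetrics:
    def test_perfect_prediction(self):
        y = ["REM", "N2", "AWA", "REM"]
        m = per_class_metrics(y, y)
        for c in ("REM", "N2", "AWA"):
            assert all(v == 1.0 for v in m.per_class[c].values())
        assert m.overall_accuracy == 1.0

    def test_hand_built_confusion_counts(self):
        """TP=90, TN=5, FP=3, FN=2 for class A reproduces the one-vs-rest
        definitions exactly."""
        y_true = ["A"] * 92 + ["B"] * 8
        y_pred = ["A"] * 90 + ["B"] * 2 + ["A"] * 3 + ["B"] * 5
        m = per_class_metrics(y_true, y_pred)
        a = m.per_class["A"]
        assert m.counts["A"] == {"TP": 90, "TN": 5, "FP": 3, "FN": 2}
        assert a["accuracy"] == pytest.approx(0.95)
        assert a["sensitivity"] == pytest.approx(90 / 92)
        assert a["specificity"] == pytest.approx(5 / 8)
        assert a["precision"] == pytest.approx(90 / 93)
        prec, sens = 90 / 93, 90 / 92
        assert a["f1"] == pytest.approx(2 * prec * sens / (prec + sens))

    def test_single_predicted_class(self):
        y_true = ["A", "B", "C", "A"]
        y_pred = ["A", "A", "A", "A"]
        m = per_class_metrics(y_true, y_pred)
        assert m.per_class["A"]["sensitivity"] == 1.0
        assert m.per_class["B"]["sensitivity"] == 0.0
        assert m.per_class["C"]["sensitivity"] == 0.0
        assert "B:precision" in m.undefined

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            per_class_metrics(["A"], ["A", "B"])

    def test_unknown_label_rejected(self):
        with pytest.raises(DataError):
            per_class_metrics(["A"], ["Z"], classes=["A", "B"])

    def test_joint_permutation_invariance(self, rng):
        y_true = rng.choice(["A", "B", "C"], 60)
        y_pred = rng.choice(["A", "B", "C"], 60)
        order = rng.permutation(60)
        m1 = per_class_metrics(y_true, y_pred)
        m2 = per_class_metrics(y_true[order], y_pred[order])
        assert m1.per_class == m2.per_class

    def test_binary_complementarity(self, rng):
        """REM sensitivity equals NREM specificity in the two-class task."""
        y_true = rng.choice(["REM", "NREM"], 200)
        y_pred = rng.choice(["REM", "NREM"], 200)
        m = per_class_metrics(y_true, y_pred)
        assert m.per_class["REM"]["sensitivity"] == \
            pytest.approx(m.per_class["NREM"]["specificity"])


class _Memorizer(BaseEstimator, ClassifierMixin):
    """Oracle that looks labels up by the identifier in column 0."""

    def __init__(self, lookup=None):
        self.lookup = lookup

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        return self

    def predict(self, X):
        return np.array([self.lookup[int(v)] for v in np.asarray(X)[:, 0]])


def _id_matrix(n, rng):
    y = rng.choice(["REM", "NREM"], n)
    X = pd.DataFrame({"id": np.arange(n, dtype=float)})
    lookup = dict(enumerate(y))
    fm = FeatureMatrix(X, pd.Series(y))
    spec = ModelSpec("custom", params={"estimator": _Memorizer(lookup)})
    return fm, spec


class TestCrossval:
    def test_loocv_covers_every_row_once(self, rng):
        fm, spec = _id_matrix(10, rng)
        m, y_true, y_pred = crossval(fm, spec, scheme="loocv", preprocess=False)
        assert len(y_true) == 10
        assert sorted(y_true) == sorted(fm.stages)

    def test_memorizing_oracle_pooled_equals_single_pass(self, rng):
        """Pooled k-fold metrics equal the one-shot metrics for an oracle."""
        fm, spec = _id_matrix(40, rng)
        m, y_true, y_pred = crossval(fm, spec, scheme="kfold", k=5,
                                     preprocess=False)
        assert np.array_equal(y_true, y_pred)
        single = per_class_metrics(fm.stages, fm.stages)
        assert m.per_class == single.per_class

    def test_holdout_is_disjoint_20_percent(self, rng):
        fm, spec = _id_matrix(100, rng)
        _, y_true, _ = crossval(fm, spec, scheme="holdout", test_fraction=0.2,
                                preprocess=False)
        assert len(y_true) == 20

    def test_kfold_fold_sizes_differ_at_most_one(self, rng):
        fm, spec = _id_matrix(23, rng)
        _, y_true, _ = crossval(fm, spec, scheme="kfold", k=4, preprocess=False)
        assert len(y_true) == 23  # partition is exhaustive

    def test_k_below_two_rejected(self, rng):
        fm, spec = _id_matrix(10, rng)
        with pytest.raises(ConfigError):
            crossval(fm, spec, scheme="kfold", k=1)


class TestFeatureTargetCorrelation:
    def test_indicator_feature_perfectly_correlated(self):
        y = ["REM", "NREM", "REM", "NREM"]
        X = pd.DataFrame({"ind": [1.0, 0.0, 1.0, 0.0],
                          "neg": [-1.0, 0.0, -1.0, 0.0]})
        corr = feature_target_correlation(FeatureMatrix(X, pd.Series(y)), "REM")
        assert corr["ind"] == pytest.approx(1.0)
        assert corr["neg"] == pytest.approx(-1.0)

    def test_independent_feature_near_zero(self, rng):
        n = 10_000
        y = rng.choice(["REM", "NREM"], n)
        X = pd.DataFrame({"noise": rng.standard_normal(n)})
        corr = feature_target_correlation(FeatureMatrix(X, pd.Series(y)), "REM")
        assert abs(corr["noise"]) < 0.05

    def test_zero_variance_column_flagged_zero(self, caplog):
        y = ["REM", "NREM"]
        X = pd.DataFrame({"const": [1.0, 1.0]})
        with caplog.at_level("WARNING"):
            corr = feature_target_correlation(FeatureMatrix(X, pd.Series(y)),
                                              "REM")
        assert corr["const"] == 0.0
        assert "zero-variance" in caplog.text


class TestHypnogramCompare:
    def test_identical_and_complementary(self):
        h1 = Hypnogram(("REM", "N2", "N3"))
        h2 = Hypnogram(("N1", "N1", "N1"))
        assert hypnogram_compare(h1, h1) == 1.0
        assert hypnogram_compare(h1, h2) == 0.0

    def test_single_mismatch_in_ten(self):
        a = Hypnogram(("N2",) * 10)
        b = Hypnogram(("N2",) * 9 + ("REM",))
        assert hypnogram_compare(a, b) == pytest.approx(0.9)

    def test_plot_file_written(self, tmp_path):
        h = Hypnogram(("AWA", "N1", "N2", "N3", "N2", "REM") * 3)
        out = tmp_path / "hyp.png"
        hypnogram_compare(h, h, plot_path=out)
        assert out.exists() and out.stat().st_size > 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            hypnogram_compare(Hypnogram(("N2",)), Hypnogram(("N2", "N2")))
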