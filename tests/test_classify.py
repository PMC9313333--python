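"""Confusion metrics, LOSOCV behaviour and leakage guarantees."""

import math

import numpy as np
import pandas as pd
import pytest

from emdhrv.classify import (
    ConfusionCounts,
    StressClassifier,
    SVMConfig,
    f1_from_precision_recall,
    losocv,
    metrics,
    sweep_feature_counts,
)
from emdhrv.errors import DataError
from emdhrv.features import FEATURE_NAMES


def synthetic_feature_table(n_subjects=12, separation=3.0, seed=0,
                            informative=("Energy", "HR")):
    """Feature table with a controllable class separation on a few
    informative columns; everything else is noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        for condition, shift in (("rest", 0.0), ("stress", separation)):
            row = {"subject_id": f"S{i:03d}", "condition": condition}
            for name in FEATURE_NAMES:
                base = shift if name in informative else 0.0
                row[name] = base + rng.standard_normal()
            rows.append(row)
    return pd.DataFrame(rows)


class TestMetrics:
    def test_f1_identity_from_reported_precision_recall(self):
        f1 = f1_from_precision_recall(87.5, 85.1)
        assert round(f1, 1) == 86.3

    def test_perfect_classification(self):
        m = metrics(ConfusionCounts(tp=5, tn=5, fp=0, fn=0))
        assert (m.accuracy, m.precision, m.recall, m.f1) == (100.0,) * 4

    def test_direct_arithmetic_case(self):
        m = metrics(ConfusionCounts(tp=3, fp=1, fn=2, tn=4))
        assert m.accuracy == pytest.approx(70.0)
        assert m.precision == pytest.approx(75.0)
        assert m.recall == pytest.approx(60.0)
        assert m.f1 == pytest.approx(200.0 / 3.0, abs=0.05)

    def test_zero_denominators_give_sentinels_not_zero(self):
        m = metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert math.isnan(m.precision)
        assert math.isnan(m.f1)
        assert m.accuracy == 100.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(DataError):
            metrics(ConfusionCounts())

    def test_accuracy_consistent_with_counts(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            tp, tn, fp, fn = rng.integers(0, 30, size=4)
            if tp + tn + fp + fn == 0:
                continue
            m = metrics(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
            assert m.accuracy == pytest.approx(
                100.0 * (tp + tn) / (tp + tn + fp + fn), abs=1e-9)


class TestLosocv:
    def test_perfectly_separable_gives_full_accuracy(self):
        table = synthetic_feature_table(separation=50.0, seed=1)
        outcome = losocv(table, svm=SVMConfig(relief_k=5), n_features=1)
        assert outcome.metrics.accuracy == 100.0

    def test_null_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(2)
        table = synthetic_feature_table(n_subjects=20, separation=0.0, seed=2)
        accuracies = []
        for _ in range(5):
            shuffled = table.copy()
            shuffled["condition"] = rng.permutation(shuffled["condition"].values)
            try:
                out = losocv(shuffled, ranking_mode="global",
                             svm=SVMConfig(relief_k=5))
                accuracies.append(out.metrics.accuracy)
            except DataError:
                continue  # a permutation can empty one class in a fold
        assert 35.0 <= np.mean(accuracies) <= 65.0

    def test_single_subject_rejected(self):
        table = synthetic_feature_table(n_subjects=1)
        with pytest.raises(DataError):
            losocv(table, svm=SVMConfig(relief_k=1))

    def test_no_leakage_from_held_out_rows(self):
        """Perturbing a held-out subject's features must not change the
        model fitted on the training fold."""
        table = synthetic_feature_table(n_subjects=8, separation=2.0, seed=3)
        X = table[FEATURE_NAMES].to_numpy()
        y = table["condition"].to_numpy()
        held = table["subject_id"] == "S000"
        train_X, train_y = X[~held.values], y[~held.values]
        clf = StressClassifier(n_features=5, relief_k=3).fit(train_X, train_y)
        reference = (clf.support_.copy(), clf.scaler_.mean_.copy(),
                     clf.svc_.coef_.copy())
        # perturb the held-out rows wildly; refit on the same training fold
        X2 = X.copy()
        X2[held.values] += 1e6
        clf2 = StressClassifier(n_features=5, relief_k=3).fit(
            X2[~held.values], train_y)
        np.testing.assert_array_equal(clf2.support_, reference[0])
        np.testing.assert_array_equal(clf2.scaler_.mean_, reference[1])
        np.testing.assert_array_equal(clf2.svc_.coef_, reference[2])

    def test_predictions_carry_subject_ids(self):
        table = synthetic_feature_table(n_subjects=6, separation=5.0, seed=4)
        outcome = losocv(table, svm=SVMConfig(relief_k=3))
        assert set(outcome.predictions["subject_id"]) == \
            set(table["subject_id"])
        assert len(outcome.predictions) == len(table)


class TestSweep:
    def test_curve_has_entry_per_feature_count(self):
        table = synthetic_feature_table(n_subjects=8, separation=4.0, seed=5)
        report = sweep_feature_counts(table, SVMConfig(relief_k=3))
        assert len(report.by_count) == 26
        assert set(report.curve()["n_features"]) == set(range(1, 27))

    def test_single_informative_feature_found_early(self):
        table = synthetic_feature_table(n_subjects=10, separation=50.0,
                                        seed=6, informative=("Energy",))
        report = sweep_feature_counts(table, SVMConfig(relief_k=4))
        assert report.best_n_features <= 3
        assert report.best.metrics.accuracy == 100.0

    def test_tie_goes_to_smaller_count(self):
        table = synthetic_feature_table(n_subjects=8, separation=50.0, seed=7)
        report = sweep_feature_counts(table, SVMConfig(relief_k=3))
        accs = report.curve().set_index("n_features")["accuracy"]
        best = report.best_n_features
        assert all(accs[n] < accs[best] for n in accs.index if n < best)
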