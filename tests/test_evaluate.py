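"""Splitting, confusion metrics, ROC/AUC, and the classifier benchmark."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import drsmargin as dm
from drsmargin.errors import (
    StratificationError,
    UndefinedMetricError,
)

from test_selection import make_table


def pair_count_auc(scores, labels):
    """Mann-Whitney oracle: concordant pairs (ties count 1/2) / (n+ * n-)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p in pos
        for n in neg
    )
    return wins / (len(pos) * len(neg))


class TestMakeSplits:
    def test_exact_divisibility(self):
        table = make_table(np.zeros((100, 2)), [1] * 60 + [0] * 40)
        splits = dm.make_splits(table, dm.CVPlan(n_folds=5, n_repeats=1, seed=0))
        y = table.y
        for _, te in splits:
            assert (y[te] == 1).sum() == 12 and (y[te] == 0).sum() == 8

    def test_partition_property(self):
        table = make_table(np.zeros((83, 2)), [1] * 50 + [0] * 33)
        plan = dm.CVPlan(n_folds=5, n_repeats=5, seed=1)
        splits = dm.make_splits(table, plan)
        assert len(splits) == 25
        for rep in range(5):
            fold_tests = [te for _, te in splits[rep * 5:(rep + 1) * 5]]
            all_te = np.concatenate(fold_tests)
            assert len(all_te) == 83 and len(set(all_te)) == 83
        for tr, te in splits:
            assert set(tr) | set(te) == set(range(83))
            assert not set(tr) & set(te)

    def test_small_class_counts_within_one_of_proportional(self):
        table = make_table(np.zeros((12, 2)), [1] * 7 + [0] * 5)
        splits = dm.make_splits(table, dm.CVPlan(n_folds=5, n_repeats=1, seed=0))
        y = table.y
        for _, te in splits:
            assert abs((y[te] == 1).sum() - 1.4) <= 1
            assert abs((y[te] == 0).sum() - 1.0) <= 1

    def test_reproducible_from_seed(self):
        table = make_table(np.zeros((40, 2)), [0, 1] * 20)
        a = dm.make_splits(table, dm.CVPlan(seed=9))
        b = dm.make_splits(table, dm.CVPlan(seed=9))
        for (tra, tea), (trb, teb) in zip(a, b):
            np.testing.assert_array_equal(tra, trb)
            np.testing.assert_array_equal(tea, teb)
        c = dm.make_splits(table, dm.CVPlan(seed=10))
        assert any(
            not np.array_equal(tea, tec) for (_, tea), (_, tec) in zip(a, c)
        )

    def test_class_smaller_than_folds_rejected(self):
        table = make_table(np.zeros((10, 2)), [1] * 3 + [0] * 7)
        with pytest.raises(StratificationError):
            dm.make_splits(table, dm.CVPlan(n_folds=5, n_repeats=1))

    def test_group_splits_keep_patients_apart(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 120)
        table = dm.FeatureTable(
            pd.DataFrame({"a": rng.random(120)}),
            np.where(y == 1, "tumor", "normal"),
            np.repeat([f"p{i}" for i in range(12)], 10),
        )
        for tr, te in dm.make_group_splits(table, dm.CVPlan(n_folds=3, n_repeats=2)):
            assert not set(table.groups[tr]) & set(table.groups[te])


class TestComputeMetrics:
    def test_worked_example(self):
        m = dm.compute_metrics(dm.ConfusionCounts(tp=9, fn=1, tn=19, fp=1))
        assert m["sensitivity"] == pytest.approx(0.90)
        assert m["specificity"] == pytest.approx(0.95)
        assert m["accuracy"] == pytest.approx(28 / 30)

    def test_perfect_and_degenerate_predictions(self):
        perfect = dm.compute_metrics(dm.ConfusionCounts(tp=5, fn=0, tn=5, fp=0))
        assert all(v == 1.0 for v in perfect.values())
        all_pos = dm.compute_metrics(dm.ConfusionCounts(tp=10, fn=0, tn=0, fp=10))
        assert all_pos["sensitivity"] == 1.0
        assert all_pos["specificity"] == 0.0
        assert all_pos["accuracy"] == 0.5

    def test_empty_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            dm.compute_metrics(dm.ConfusionCounts(tp=3, fn=2, tn=0, fp=0))

    @given(
        tp=st.integers(0, 50), fn=st.integers(0, 50),
        tn=st.integers(0, 50), fp=st.integers(0, 50),
    )
    @settings(max_examples=200, deadline=None)
    def test_accuracy_prevalence_identity(self, tp, fn, tn, fp):
        """accuracy = prevalence * sensitivity + (1 - prevalence) * specificity."""
        if tp + fn == 0 or tn + fp == 0:
            return
        counts = dm.ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)
        m = dm.compute_metrics(counts)
        prev = (tp + fn) / counts.total
        assert m["accuracy"] == pytest.approx(
            prev * m["sensitivity"] + (1 - prev) * m["specificity"]
        )


class TestRocAndAuc:
    def test_perfect_separation(self):
        _, auc = dm.roc_and_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0

    def test_worked_example_matches_pair_oracle(self):
        scores = [0.1, 0.4, 0.35, 0.8]
        labels = [0, 0, 1, 1]
        _, auc = dm.roc_and_auc(scores, labels)
        assert auc == pytest.approx(0.75)
        assert auc == pytest.approx(pair_count_auc(scores, labels))

    def test_permutation_null(self):
        rng = np.random.default_rng(0)
        scores = rng.random(2000)
        labels = rng.permutation(np.repeat([0, 1], 1000))
        _, auc = dm.roc_and_auc(scores, labels)
        assert abs(auc - 0.5) < 0.03

    def test_exhaustive_small_cases_match_pair_oracle(self):
        """All label arrangements of 8 samples (scores with ties) equal the
        brute-force Mann-Whitney pair count."""
        rng = np.random.default_rng(1)
        scores = np.round(rng.random(8), 1)  # rounding forces ties
        for k in range(1, 8):
            for pos in itertools.combinations(range(8), k):
                labels = np.zeros(8, dtype=int)
                labels[list(pos)] = 1
                _, auc = dm.roc_and_auc(scores, labels)
                assert auc == pytest.approx(pair_count_auc(scores, labels))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, 100)
        if len(np.unique(labels)) < 2:
            labels[0] = 1 - labels[0]
        _, a = dm.roc_and_auc(scores, labels)
        _, b = dm.roc_and_auc(np.exp(3 * scores) + 7, labels)
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            dm.roc_and_auc([0.1, 0.2], [1, 1])


class TestRunBenchmark:
    def _separable_table(self, n=150, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.permutation(np.repeat([0, 1], n // 2))
        X = rng.normal(size=(n, 2)) + np.where(y[:, None] == 1, 6.0, 0.0)
        return make_table(X, y)

    def test_separable_classes_all_classifiers_near_perfect(self):
        report = dm.run_benchmark(
            self._separable_table(), dm.CVPlan(n_folds=5, n_repeats=2, seed=0)
        )
        agg = report.aggregate()
        assert (agg["accuracy_mean"] >= 0.99).all()
        assert not report.failures

    def test_permuted_labels_drive_auc_to_half(self):
        rng = np.random.default_rng(3)
        table = self._separable_table(n=200, seed=3)
        permuted = dm.FeatureTable(
            table.features,
            rng.permutation(table.labels),
            table.groups,
        )
        report = dm.run_benchmark(
            permuted,
            dm.CVPlan(n_folds=5, n_repeats=2, seed=0),
            classifiers=("linear_svm", "lgbm"),
        )
        agg = report.aggregate()
        assert (abs(agg["auc_mean"] - 0.5) < 0.07).all()

    def test_aggregates_recomputable_from_splits(self):
        report = dm.run_benchmark(
            self._separable_table(), dm.CVPlan(n_folds=5, n_repeats=2, seed=1)
        )
        agg = report.aggregate().set_index("classifier")
        for clf, grp in report.per_split.groupby("classifier"):
            for m in report.METRICS:
                assert agg.loc[clf, f"{m}_mean"] == pytest.approx(
                    grp[m].mean(), abs=1e-12
                )
                assert agg.loc[clf, f"{m}_sd"] == pytest.approx(
                    grp[m].std(ddof=1), abs=1e-12
                )

    def test_failing_classifier_surfaced_not_fatal(self):
        class Exploding:
            def fit(self, X, y):
                raise RuntimeError("boom")

        table = self._separable_table()
        report = dm.run_benchmark(
            table, dm.CVPlan(n_folds=5, n_repeats=1, seed=0),
            classifiers=(Exploding(), "linear_svm"),
        )
        failed = report.per_split[report.per_split["failed"]]
        assert len(failed) == 5 and len(report.failures) == 5
        agg = report.aggregate()
        assert list(agg["classifier"]) == ["linear_svm"]

    def test_report_serialisation(self, tmp_path):
        report = dm.run_benchmark(
            self._separable_table(), dm.CVPlan(n_folds=3, n_repeats=1, seed=0),
            classifiers=("linear_svm",),
        )
        report.to_csv(tmp_path / "r.csv")
        report.to_json(tmp_path / "r.json")
        import json

        payload = json.loads((tmp_path / "r.json").read_text())
        assert payload["plan"]["n_folds"] == 3
        assert "linear_svm" in payload["aggregate"]
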