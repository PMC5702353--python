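"""Fold assignment, metric formulas (vs brute-force oracle), CV harness."""

import numpy as np
import pytest

from wavecog import (
    ClassifierSpec,
    ConfusionCounts,
    FeatureMatrix,
    default_classifier_specs,
    evaluate,
    kfold_assign,
    metrics_from_confusion,
)


class TestKfoldAssign:
    def test_balanced_560(self):
        labels = np.array([1, 2] * 280)
        fa = kfold_assign(labels, k=10, seed=0)
        for f in range(10):
            mask = fa.fold_index == f
            assert mask.sum() == 56
            assert (labels[mask] == 1).sum() == 28

    def test_tiny_folds(self):
        labels = np.array([1, 2] * 10)
        fa = kfold_assign(labels, k=10, seed=1)
        assert all((fa.fold_index == f).sum() == 2 for f in range(10))

    def test_deterministic(self):
        labels = np.array([1, 2] * 30)
        a = kfold_assign(labels, k=10, seed=5)
        b = kfold_assign(labels, k=10, seed=5)
        assert np.array_equal(a.fold_index, b.fold_index)

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(ValueError, match="fewer than"):
            kfold_assign(np.array([1] * 5 + [2] * 20), k=10, seed=0)

    def test_unstratified_sizes(self):
        fa = kfold_assign(np.array([1, 2] * 12), k=5, seed=0, stratified=False)
        sizes = [(fa.fold_index == f).sum() for f in range(5)]
        assert max(sizes) - min(sizes) <= 1


def _brute_force_metrics(tp, fn, tn, fp):
    """Independent direct transcription of the percent/kappa formulas."""
    n = tp + fn + tn + fp
    acc = (tp + tn) / n * 100
    sens = tp / (tp + fn) * 100 if tp + fn else None
    spec = tn / (tn + fp) * 100 if tn + fp else None
    prec = tp / (tp + fp) * 100 if tp + fp else None
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    kappa = (po - pe) / (1 - pe) if pe < 1 else None
    return acc, sens, spec, prec, kappa


class TestMetrics:
    def test_perfect_classifier(self):
        m = metrics_from_confusion(ConfusionCounts(tp=280, tn=280))
        assert (m.accuracy, m.sensitivity, m.specificity, m.precision) == (
            100.0, 100.0, 100.0, 100.0,
        )
        assert m.kappa == 1.0

    def test_worked_example(self):
        m = metrics_from_confusion(ConfusionCounts(tp=45, fn=5, tn=40, fp=10))
        assert m.accuracy == pytest.approx(85.0)
        assert m.sensitivity == pytest.approx(90.0)
        assert m.specificity == pytest.approx(80.0)
        assert m.precision == pytest.approx(81.8181818, abs=1e-4)
        assert m.kappa == pytest.approx(0.70)

    def test_all_one_class_predictions(self):
        m = metrics_from_confusion(ConfusionCounts(tp=50, fp=50))
        assert m.accuracy == 50.0
        assert m.kappa == 0.0

    def test_undefined_metrics_reported_not_coerced(self):
        m = metrics_from_confusion(ConfusionCounts(tn=5, fp=5))
        assert m.sensitivity is None
        assert "sensitivity" in m.undefined

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)

    def test_matches_brute_force_oracle_on_random_tables(self, rng):
        for _ in range(1000):
            tp, fn, tn, fp = rng.integers(0, 40, size=4)
            if tp + fn + tn + fp == 0:
                continue
            m = metrics_from_confusion(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            acc, sens, spec, prec, kappa = _brute_force_metrics(tp, fn, tn, fp)
            assert m.accuracy == pytest.approx(acc)
            for got, want in [
                (m.sensitivity, sens), (m.specificity, spec),
                (m.precision, prec), (m.kappa, kappa),
            ]:
                if want is None:
                    assert got is None
                else:
                    assert got == pytest.approx(want)

    def test_auc_from_scores(self):
        # wins of {2,3,5} over {1,4}: (2>1),(3>1),(5>1),(5>4) -> 4 of 6 pairs
        truth = np.array([1, 1, 1, 2, 2])
        scores = np.array([2.0, 3.0, 5.0, 1.0, 4.0])
        m = metrics_from_confusion(
            ConfusionCounts(tp=2, fn=1, tn=1, fp=1), scores, truth
        )
        assert m.auc == pytest.approx(4 / 6)


def _separable_matrices(n=30):
    """One feature determines the label with a wide margin."""
    rng = np.random.default_rng(0)
    x = rng.normal(size=(2 * n, 4))
    x[:, 0] = np.r_[rng.uniform(5, 6, n), rng.uniform(-6, -5, n)]
    labels = np.array([1] * n + [2] * n)
    m = FeatureMatrix(values=x, labels=labels,
                      feature_names=["a", "b", "c", "d"], band="A5")
    return {"A5": m}


class TestEvaluate:
    def test_separable_data_perfect_knn_svm(self):
        mats = _separable_matrices()
        folds = kfold_assign(mats["A5"].labels, k=10, seed=0)
        specs = [ClassifierSpec("knn", {"k": 3}), ClassifierSpec("svm_rbf")]
        rep = evaluate(mats, specs, folds)
        for r in rep.results:
            assert r.metrics.accuracy == 100.0

    def test_every_instance_tested_once(self, small_matrices):
        mats = {b: small_matrices[b] for b in ("A5", "D5")}
        n = mats["A5"].n_instances
        folds = kfold_assign(mats["A5"].labels, k=10, seed=3)
        rep = evaluate(mats, default_classifier_specs(), folds)
        assert len(rep.results) == 8
        for r in rep.results:
            assert r.confusion.total == n
            assert sum(m_.accuracy is not None for m_ in r.per_fold) == 10

    def test_report_regeneration_identical(self, small_matrices):
        mats = {"A5": small_matrices["A5"]}
        folds = kfold_assign(mats["A5"].labels, k=10, seed=3)
        specs = default_classifier_specs(seed=1)
        r1 = evaluate(mats, specs, folds)
        r2 = evaluate(mats, specs, folds)
        assert r1.to_json() == r2.to_json()

    def test_d1_excluded_by_default(self, small_matrices):
        rep = evaluate(small_matrices, default_classifier_specs()[:1])
        assert {r.band for r in rep.results} == {"A5", "D5", "D4", "D3", "D2"}

    def test_mismatched_labels_rejected(self, small_matrices):
        bad = FeatureMatrix(
            values=small_matrices["A5"].values,
            labels=small_matrices["A5"].labels[::-1],
            feature_names=small_matrices["A5"].feature_names,
            band="D5",
        )
        with pytest.raises(ValueError, match="mismatched labels"):
            evaluate({"A5": small_matrices["A5"], "D5": bad})

    def test_unknown_classifier_rejected(self, small_matrices):
        spec = ClassifierSpec.__new__(ClassifierSpec)
        object.__setattr__(spec, "name", "boosted_stump")
        object.__setattr__(spec, "hyperparameters", {})
        object.__setattr__(spec, "seed", 0)
        with pytest.raises(ValueError, match="unknown classifier"):
            evaluate({"A5": small_matrices["A5"]}, [spec])

    def test_global_fit_at_least_as_optimistic(self, small_matrices):
        mats = {"A5": small_matrices["A5"], "D4": small_matrices["D4"]}
        folds = kfold_assign(mats["A5"].labels, k=10, seed=0)
        specs = [ClassifierSpec("knn", {"k": 3})]
        fold_rep = evaluate(mats, specs, folds, leakage_mode="foldwise")
        glob_rep = evaluate(mats, specs, folds, leakage_mode="paper_global")
        mean_fold = np.mean([r.metrics.accuracy for r in fold_rep.results])
        mean_glob = np.mean([r.metrics.accuracy for r in glob_rep.results])
        assert mean_glob >= mean_fold - 5.0  # allow small-sample wobble
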