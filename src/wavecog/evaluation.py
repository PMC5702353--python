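"""Cross-validated classifier benchmarking with a full metric set.

Four classifiers — KNN (k=3), SVM with an RBF kernel, a one-hidden-layer
MLP (5 logistic units) and Gaussian naive Bayes — are evaluated with
stratified 10-fold cross-validation on each sub-band's selected features.
Classifier training is delegated to scikit-learn; the fold assignment,
confusion bookkeeping and every metric are implemented here so they can
be checked against brute-force oracles.

Two leakage modes control where normalization and feature selection are
fitted:

* ``foldwise`` (default, unbiased): z-scoring, FDR ranking and PCA are
  fitted on the nine training folds only and applied to the held-out fold.
* ``paper_global`` (optimistic): the preprocessing pipeline is fitted once
  on the full dataset before cross-validation, the procedure implied when
  a study standardizes and selects features prior to CV.

Class 1 (the cognitive-task condition) is the positive class throughout;
sensitivity, specificity and precision are reported from its standpoint.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .features import EXCLUDED_BY_DEFAULT, FeatureMatrix
from .prep import apply_zscore, feature_overlap_auc, fit_zscore
from .selection import FDRVariant, select_features

__all__ = [
    "ClassifierSpec",
    "FoldAssignment",
    "ConfusionCounts",
    "MetricSet",
    "PerformanceReport",
    "default_classifier_specs",
    "kfold_assign",
    "metrics_from_confusion",
    "evaluate",
]

LeakageMode = Literal["foldwise", "paper_global"]
POSITIVE_CLASS = 1


@dataclass(frozen=True)
class ClassifierSpec:
    """Named classifier with its hyperparameters and a seed.

    The seed feeds MLP weight initialization (KNN, SVM and naive Bayes are
    deterministic here).
    """

    name: Literal["knn", "svm_rbf", "mlp", "naive_bayes"]
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def build(self):
        hp = dict(self.hyperparameters)
        if self.name == "knn":
            return KNeighborsClassifier(n_neighbors=hp.pop("k", 3), **hp)
        if self.name == "svm_rbf":
            return SVC(
                kernel="rbf", C=hp.pop("C", 1.0), gamma=hp.pop("gamma", "scale"), **hp
            )
        if self.name == "mlp":
            return MLPClassifier(
                hidden_layer_sizes=(hp.pop("hidden_units", 5),),
                activation=hp.pop("activation", "logistic"),
                max_iter=hp.pop("max_iter", 1000),
                random_state=self.seed,
                **hp,
            )
        if self.name == "naive_bayes":
            return GaussianNB(**hp)
        raise ValueError(f"unknown classifier {self.name!r}")


def default_classifier_specs(seed: int = 0) -> list[ClassifierSpec]:
    return [
        ClassifierSpec("knn", {"k": 3}, seed),
        ClassifierSpec("svm_rbf", {"C": 1.0, "gamma": "scale"}, seed),
        ClassifierSpec("mlp", {"hidden_units": 5}, seed),
        ClassifierSpec("naive_bayes", {}, seed),
    ]


@dataclass
class FoldAssignment:
    fold_index: np.ndarray
    k: int
    seed: int
    stratified: bool


def kfold_assign(
    labels: np.ndarray, k: int = 10, seed: int = 0, stratified: bool = True
) -> FoldAssignment:
    """Assign every instance to one of ``k`` folds.

    Seeded shuffle followed by round-robin assignment (within each class
    when stratified), so fold sizes differ by at most one — and per-class
    fold counts differ by at most one under stratification.
    """
    labels = np.asarray(labels, dtype=int)
    n = labels.size
    if k < 2 or k > n:
        raise ValueError(f"k must be in [2, n]; got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    fold = np.empty(n, dtype=int)
    groups = (
        [np.flatnonzero(labels == c) for c in np.unique(labels)]
        if stratified
        else [np.arange(n)]
    )
    for idx in groups:
        if stratified and idx.size < k:
            raise ValueError(
                f"a class has {idx.size} instances, fewer than k={k} folds"
            )
        perm = rng.permutation(idx)
        fold[perm] = np.arange(perm.size) % k
    return FoldAssignment(fold_index=fold, k=k, seed=seed, stratified=stratified)


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(
        cls, truth: np.ndarray, predicted: np.ndarray
    ) -> "ConfusionCounts":
        truth = np.asarray(truth)
        predicted = np.asarray(predicted)
        pos_t = truth == POSITIVE_CLASS
        pos_p = predicted == POSITIVE_CLASS
        return cls(
            tp=int(np.sum(pos_t & pos_p)),
            fp=int(np.sum(~pos_t & pos_p)),
            tn=int(np.sum(~pos_t & ~pos_p)),
            fn=int(np.sum(pos_t & ~pos_p)),
        )


@dataclass
class MetricSet:
    """Percent metrics plus AUC (fraction) and Cohen's kappa.

    A metric whose denominator is zero is reported as ``None`` with the
    reason recorded in ``undefined`` rather than coerced to 0.
    """

    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    precision: float | None = None
    auc: float | None = None
    kappa: float | None = None
    undefined: dict[str, str] = field(default_factory=dict)


def metrics_from_confusion(
    counts: ConfusionCounts,
    scores: np.ndarray | None = None,
    truth: np.ndarray | None = None,
) -> MetricSet:
    """Accuracy / sensitivity / specificity / precision (%), kappa, AUC.

    Kappa is chance-corrected agreement (Po - Pe) / (1 - Pe) with Pe the
    sum over classes of predicted-marginal x true-marginal.  AUC, when
    per-instance decision scores and truth are supplied, is the rank
    statistic (ties counted half) with higher scores meaning "more
    positive".
    """
    n = counts.total
    if n == 0:
        raise ValueError("empty confusion table")
    out = MetricSet()
    out.accuracy = 100.0 * (counts.tp + counts.tn) / n
    if counts.tp + counts.fn > 0:
        out.sensitivity = 100.0 * counts.tp / (counts.tp + counts.fn)
    else:
        out.undefined["sensitivity"] = "no positive instances"
    if counts.tn + counts.fp > 0:
        out.specificity = 100.0 * counts.tn / (counts.tn + counts.fp)
    else:
        out.undefined["specificity"] = "no negative instances"
    if counts.tp + counts.fp > 0:
        out.precision = 100.0 * counts.tp / (counts.tp + counts.fp)
    else:
        out.undefined["precision"] = "no positive predictions"
    po = (counts.tp + counts.tn) / n
    pred_pos = (counts.tp + counts.fp) / n
    true_pos = (counts.tp + counts.fn) / n
    pe = pred_pos * true_pos + (1 - pred_pos) * (1 - true_pos)
    if pe < 1.0:
        out.kappa = (po - pe) / (1.0 - pe)
    else:
        out.undefined["kappa"] = "chance agreement is 1"
    if scores is not None and truth is not None:
        binary = np.where(np.asarray(truth) == POSITIVE_CLASS, 1, 2)
        raw, _ = feature_overlap_auc(np.asarray(scores, float), binary)
        out.auc = raw
    return out


def _positive_scores(clf, x: np.ndarray) -> np.ndarray:
    """Per-instance score, larger = more likely the positive class."""
    if hasattr(clf, "decision_function"):
        d = clf.decision_function(x)
        # sklearn's decision function is oriented toward classes_[1]
        return d if clf.classes_[1] == POSITIVE_CLASS else -d
    proba = clf.predict_proba(x)
    col = int(np.flatnonzero(clf.classes_ == POSITIVE_CLASS)[0])
    return proba[:, col]


@dataclass
class BandClassifierResult:
    band: str
    classifier: str
    confusion: ConfusionCounts
    metrics: MetricSet
    per_fold: list[MetricSet]


@dataclass
class PerformanceReport:
    results: list[BandClassifierResult]
    config: dict

    def to_table(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "band": r.band,
                    "classifier": r.classifier,
                    "accuracy_pct": r.metrics.accuracy,
                    "sensitivity_pct": r.metrics.sensitivity,
                    "specificity_pct": r.metrics.specificity,
                    "auc": r.metrics.auc,
                    "precision_pct": r.metrics.precision,
                    "kappa": r.metrics.kappa,
                }
            )
        return pd.DataFrame(rows)

    def to_json(self, **kwargs) -> str:
        payload = {
            "config": self.config,
            "results": [
                {
                    "band": r.band,
                    "classifier": r.classifier,
                    "confusion": asdict(r.confusion),
                    "metrics": asdict(r.metrics),
                    "per_fold": [asdict(m) for m in r.per_fold],
                }
                for r in self.results
            ],
        }
        return json.dumps(payload, indent=2, **kwargs)

    def get(self, band: str, classifier: str) -> BandClassifierResult:
        for r in self.results:
            if r.band == band and r.classifier == classifier:
                return r
        raise KeyError(f"no result for band={band!r}, classifier={classifier!r}")


def _prep_fold(
    matrix: FeatureMatrix,
    train: np.ndarray,
    test: np.ndarray,
    leakage_mode: LeakageMode,
    variance_target: float,
    fdr_variant: FDRVariant,
):
    """Fit z-scoring + selection per the leakage mode; return train/test arrays."""

    def subset(rows: np.ndarray) -> FeatureMatrix:
        return FeatureMatrix(
            values=matrix.values[rows],
            labels=matrix.labels[rows],
            feature_names=list(matrix.feature_names),
            band=matrix.band,
        )

    if leakage_mode == "paper_global":
        fit_on = matrix
    elif leakage_mode == "foldwise":
        fit_on = subset(train)
    else:
        raise ValueError(f"unknown leakage mode {leakage_mode!r}")
    params = fit_zscore(fit_on)
    sel = select_features(apply_zscore(fit_on, params), variance_target, fdr_variant)
    tr = sel.transform(apply_zscore(subset(train), params))
    te = sel.transform(apply_zscore(subset(test), params))
    return tr, te


def evaluate(
    matrices: dict[str, FeatureMatrix],
    specs: list[ClassifierSpec] | None = None,
    folds: FoldAssignment | None = None,
    leakage_mode: LeakageMode = "foldwise",
    variance_target: float = 0.95,
    fdr_variant: FDRVariant = "canonical",
    exclude_bands: tuple[str, ...] = EXCLUDED_BY_DEFAULT,
) -> PerformanceReport:
    """Cross-validate every classifier on every (non-excluded) band matrix.

    Confusion counts are pooled over folds (every instance is tested
    exactly once), per-fold metrics are retained, and pooled AUC is
    computed from the held-out decision scores of all folds.
    """
    bands = [b for b in matrices if b not in exclude_bands]
    if not bands:
        raise ValueError("no bands left to evaluate after exclusion")
    ref = matrices[bands[0]]
    for b in bands:
        if not np.array_equal(matrices[b].labels, ref.labels):
            raise ValueError(f"band {b!r} has mismatched labels")
    if specs is None:
        specs = default_classifier_specs()
    if folds is None:
        folds = kfold_assign(ref.labels, k=10, seed=0, stratified=True)
    if folds.fold_index.size != ref.n_instances:
        raise ValueError("fold assignment size does not match instance count")

    results: list[BandClassifierResult] = []
    for band in bands:
        matrix = matrices[band]
        # preprocessing is classifier-independent: do it once per fold
        prepped = []
        for f in range(folds.k):
            test = np.flatnonzero(folds.fold_index == f)
            train = np.flatnonzero(folds.fold_index != f)
            tr, te = _prep_fold(
                matrix, train, test, leakage_mode, variance_target, fdr_variant
            )
            prepped.append((test, tr, te))
        for spec in specs:
            predicted = np.empty(matrix.n_instances, dtype=int)
            score = np.empty(matrix.n_instances, dtype=float)
            per_fold = []
            for test, tr, te in prepped:
                clf = spec.build()
                with warnings.catch_warnings():
                    # the MLP runs a fixed iteration budget by design
                    from sklearn.exceptions import ConvergenceWarning

                    warnings.simplefilter("ignore", ConvergenceWarning)
                    clf.fit(tr.values, tr.labels)
                predicted[test] = clf.predict(te.values)
                score[test] = _positive_scores(clf, te.values)
                fold_counts = ConfusionCounts.from_predictions(
                    te.labels, predicted[test]
                )
                per_fold.append(
                    metrics_from_confusion(fold_counts, score[test], te.labels)
                )
            pooled = ConfusionCounts.from_predictions(matrix.labels, predicted)
            metrics = metrics_from_confusion(pooled, score, matrix.labels)
            results.append(
                BandClassifierResult(
                    band=band,
                    classifier=spec.name,
                    confusion=pooled,
                    metrics=metrics,
                    per_fold=per_fold,
                )
            )
    config = {
        "leakage_mode": leakage_mode,
        "variance_target": variance_target,
        "fdr_variant": fdr_variant,
        "excluded_bands": list(exclude_bands),
        "k": folds.k,
        "fold_seed": folds.seed,
        "stratified": folds.stratified,
        "classifiers": [
            {"name": s.name, "hyperparameters": s.hyperparameters, "seed": s.seed}
            for s in specs
        ],
        "positive_class": POSITIVE_CLASS,
    }
    return PerformanceReport(results=results, config=config)
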