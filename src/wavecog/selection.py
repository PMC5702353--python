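"""Feature selection: Fisher-discriminant-ratio ranking then PCA.

The selection stage has two steps, run independently per sub-band:

1. Score every feature with Fisher's discriminant ratio
   FDR = (m1 - m2)^2 / (s1^2 + s2^2), rank descending, and keep the
   above-median half (the top ``ceil(p/2)`` features, deterministic
   tie-break by original index).
2. Fit PCA on the kept columns and retain the smallest number of
   components whose cumulative eigenvalue fraction reaches the variance
   target (default 95%); the component scores are the classifier input.

An ``as_printed`` FDR variant, |m1 - m2| / |s1^2 - s2^2|, is provided for
side-by-side comparison with a formulation occasionally seen in the
applied literature; it is not scale-invariant and is never the default.
Selection is fully deterministic: same matrix in, same result out.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .features import FeatureMatrix

__all__ = [
    "FDRScores",
    "PCAModel",
    "SelectionResult",
    "fdr_scores",
    "select_above_median",
    "pca_fit",
    "pca_transform",
    "select_features",
]

FDRVariant = Literal["canonical", "as_printed"]

# floor applied only when a denominator is exactly 0 while means differ
_DENOM_EPS = 1e-12


@dataclass
class FDRScores:
    scores: np.ndarray
    variant: FDRVariant
    class_means: tuple[np.ndarray, np.ndarray]       # (m1, m2) per feature
    class_variances: tuple[np.ndarray, np.ndarray]   # (s1^2, s2^2) per feature
    floored: np.ndarray = None  # bool mask of features whose denominator was floored


@dataclass
class PCAModel:
    """Centering vector, orthonormal components (features x m), eigenvalues."""

    center: np.ndarray
    components: np.ndarray
    eigenvalues: np.ndarray
    m: int
    variance_captured: float


@dataclass
class SelectionResult:
    kept_feature_indices: np.ndarray
    fdr: FDRScores
    pca: PCAModel
    transformed: FeatureMatrix

    def transform(self, matrix: FeatureMatrix) -> FeatureMatrix:
        """Apply the fitted selection to new data (same original features)."""
        sub = FeatureMatrix(
            values=matrix.values[:, self.kept_feature_indices],
            labels=matrix.labels,
            feature_names=[
                matrix.feature_names[i] for i in self.kept_feature_indices
            ],
            band=matrix.band,
        )
        return pca_transform(self.pca, sub)


def fdr_scores(
    matrix: FeatureMatrix, variant: FDRVariant = "canonical"
) -> FDRScores:
    """Per-feature class-discrimination scores.

    Class variances are population variances.  If both class variances of
    a feature are exactly zero while the means differ, the denominator is
    floored at 1e-12 (yielding a very large score) and the feature is
    flagged in ``floored``.
    """
    if matrix.n_features == 0:
        raise ValueError("empty feature matrix")
    mask1 = matrix.labels == 1
    mask2 = ~mask1
    if mask1.sum() < 2 or mask2.sum() < 2:
        raise ValueError("each class needs at least 2 instances")
    x1, x2 = matrix.values[mask1], matrix.values[mask2]
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    v1, v2 = x1.var(axis=0, ddof=0), x2.var(axis=0, ddof=0)
    if variant == "canonical":
        num = (m1 - m2) ** 2
        denom = v1 + v2
    elif variant == "as_printed":
        num = np.abs(m1 - m2)
        denom = np.abs(v1 - v2)
    else:
        raise ValueError(f"unknown FDR variant {variant!r}")
    floored = (denom == 0.0) & (num > 0.0)
    safe = np.where(denom == 0.0, _DENOM_EPS, denom)
    scores = np.where((denom == 0.0) & (num == 0.0), 0.0, num / safe)
    return FDRScores(
        scores=scores,
        variant=variant,
        class_means=(m1, m2),
        class_variances=(v1, v2),
        floored=floored,
    )


def select_above_median(scores: FDRScores) -> np.ndarray:
    """Indices of the top ``ceil(p/2)`` features by score.

    Ranking is by score descending with ties broken by ascending original
    index; the kept indices are returned sorted ascending.
    """
    s = np.asarray(scores.scores, dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 features to take an above-median subset")
    order = np.lexsort((np.arange(s.size), -s))  # score desc, index asc
    keep = int(np.ceil(s.size / 2))
    return np.sort(order[:keep])


def pca_fit(matrix: FeatureMatrix, variance_target: float = 0.95) -> PCAModel:
    """PCA via SVD of the centered data; retain to the variance target.

    ``m`` is the smallest component count whose cumulative eigenvalue
    fraction reaches ``variance_target``.  Component signs are fixed so
    each column's largest-magnitude entry is positive.  Eigenvalues use
    the 1/(N-1) covariance normalization; variance fractions do not
    depend on that choice.
    """
    if matrix.n_instances < 2 or matrix.n_features < 1:
        raise ValueError("need at least 2 instances and 1 feature")
    if not 0.0 < variance_target <= 1.0:
        raise ValueError("variance_target must be in (0, 1]")
    center = matrix.values.mean(axis=0)
    xc = matrix.values - center
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    eig = s**2 / (matrix.n_instances - 1)
    total = eig.sum()
    if total == 0.0:
        raise ValueError("rank-0 matrix: all instances identical")
    # drop numerically-zero directions so components stay well defined
    nonzero = eig > total * 1e-12
    eig, vt = eig[nonzero], vt[nonzero]
    frac = np.cumsum(eig) / total
    m = int(np.searchsorted(frac, variance_target - 1e-12) + 1)
    m = min(m, eig.size)
    components = vt[:m].T
    sign = np.sign(components[np.abs(components).argmax(axis=0), np.arange(m)])
    sign[sign == 0] = 1.0
    return PCAModel(
        center=center,
        components=components * sign,
        eigenvalues=eig,
        m=m,
        variance_captured=float(frac[m - 1]),
    )


def pca_transform(model: PCAModel, matrix: FeatureMatrix) -> FeatureMatrix:
    """Project instances onto the retained components: y = A^T (x - center)."""
    if matrix.n_features != model.center.size:
        raise ValueError(
            f"feature count mismatch: matrix has {matrix.n_features}, "
            f"model expects {model.center.size}"
        )
    y = (matrix.values - model.center) @ model.components
    return FeatureMatrix(
        values=y,
        labels=matrix.labels,
        feature_names=[f"PC{i + 1}" for i in range(model.m)],
        band=matrix.band,
    )


def select_features(
    matrix: FeatureMatrix,
    variance_target: float = 0.95,
    variant: FDRVariant = "canonical",
) -> SelectionResult:
    """FDR ranking, above-median subset, then PCA on the kept columns."""
    fdr = fdr_scores(matrix, variant)
    kept = select_above_median(fdr)
    sub = FeatureMatrix(
        values=matrix.values[:, kept],
        labels=matrix.labels,
        feature_names=[matrix.feature_names[i] for i in kept],
        band=matrix.band,
    )
    pca = pca_fit(sub, variance_target)
    transformed = pca_transform(pca, sub)
    return SelectionResult(
        kept_feature_indices=kept, fdr=fdr, pca=pca, transformed=transformed
    )
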