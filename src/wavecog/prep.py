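"""Feature standardization and per-feature class-overlap diagnostics.

Features are z-scored to zero mean and unit variance (population
convention).  The fit/apply split matters: fitting on all data before
cross-validation leaks test-set statistics into training, so the
evaluation harness fits these parameters on training folds only unless
explicitly asked to reproduce the global-fit procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureMatrix

__all__ = [
    "NormParams",
    "FeatureDiagnostics",
    "fit_zscore",
    "apply_zscore",
    "feature_overlap_auc",
    "diagnostics",
]


@dataclass
class NormParams:
    """Per-feature mean/standard deviation (population), plus fit size."""

    mu: np.ndarray
    sigma: np.ndarray
    fitted_on: int

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.shape != self.sigma.shape or self.mu.ndim != 1:
            raise ValueError("mu and sigma must be 1-D of equal length")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")


@dataclass
class FeatureDiagnostics:
    """Summary table plus histograms, one row/entry per feature."""

    summary: pd.DataFrame            # mean, std, skewness, auc_raw, auc_folded
    histograms: list[tuple[np.ndarray, np.ndarray]]  # (counts, bin_edges)


def fit_zscore(matrix: FeatureMatrix) -> NormParams:
    """Population mean and standard deviation of each feature column."""
    if matrix.n_instances < 2:
        raise ValueError("need at least 2 instances to fit normalization")
    return NormParams(
        mu=matrix.values.mean(axis=0),
        sigma=matrix.values.std(axis=0, ddof=0),
        fitted_on=matrix.n_instances,
    )


def apply_zscore(matrix: FeatureMatrix, params: NormParams) -> FeatureMatrix:
    """(x - mu) / sigma per feature; zero-variance features map to 0."""
    if matrix.n_features != params.mu.size:
        raise ValueError(
            f"feature count mismatch: matrix has {matrix.n_features}, "
            f"params fitted on {params.mu.size}"
        )
    sigma = params.sigma.copy()
    degenerate = sigma == 0.0
    if np.any(degenerate):
        names = [matrix.feature_names[i] for i in np.flatnonzero(degenerate)]
        warnings.warn(
            f"zero-variance features mapped to 0: {names}", stacklevel=2
        )
        sigma[degenerate] = 1.0
    z = (matrix.values - params.mu) / sigma
    z[:, degenerate] = 0.0
    return FeatureMatrix(
        values=z,
        labels=matrix.labels,
        feature_names=list(matrix.feature_names),
        band=matrix.band,
    )


def feature_overlap_auc(
    values: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """Rank-based two-sample AUC of one feature column.

    Returns ``(raw, folded)``: *raw* is the probability that a random
    class-1 value exceeds a random class-2 value (ties counted half), the
    Mann-Whitney U statistic scaled to [0, 1]; *folded* is
    ``max(raw, 1 - raw)`` so 0.5 means complete class overlap and 1 means
    complete separation regardless of direction.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    mask1 = labels == 1
    n1 = int(mask1.sum())
    n2 = int(labels.size - n1)
    if n1 == 0 or n2 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(values)  # midranks handle ties at 1/2
    u1 = ranks[mask1].sum() - n1 * (n1 + 1) / 2.0
    raw = float(u1 / (n1 * n2))
    return raw, max(raw, 1.0 - raw)


def _histogram(col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Freedman-Diaconis bin count with a floor of 10 bins
    iqr = np.subtract(*np.percentile(col, [75, 25]))
    span = col.max() - col.min()
    if iqr > 0 and span > 0:
        width = 2.0 * iqr / col.size ** (1.0 / 3.0)
        bins = max(10, int(np.ceil(span / width)))
    else:
        bins = 10
    return np.histogram(col, bins=bins)


def diagnostics(matrix: FeatureMatrix) -> FeatureDiagnostics:
    """Per-feature distribution summary and class-overlap AUC.

    Pure computation; any plotting is left to callers.
    """
    rows = []
    hists = []
    for j, name in enumerate(matrix.feature_names):
        col = matrix.values[:, j]
        raw, folded = feature_overlap_auc(col, matrix.labels)
        rows.append(
            {
                "feature": name,
                "mean": col.mean(),
                "std": col.std(ddof=0),
                "skewness": float(stats.skew(col)) if col.std() > 0 else 0.0,
                "auc_raw": raw,
                "auc_folded": folded,
            }
        )
        hists.append(_histogram(col))
    return FeatureDiagnostics(summary=pd.DataFrame(rows), histograms=hists)
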