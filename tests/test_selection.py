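"""FDR ranking, above-median subset rule, and PCA retention."""

import numpy as np
import pytest

from wavecog import (
    FeatureMatrix,
    fdr_scores,
    pca_fit,
    pca_transform,
    select_above_median,
    select_features,
)


def _matrix(values, labels):
    values = np.asarray(values, float)
    return FeatureMatrix(
        values=values,
        labels=np.asarray(labels),
        feature_names=[f"f{i}" for i in range(values.shape[1])],
    )


def _two_class(rng, n=40, p=6, shift=None):
    x = rng.normal(size=(2 * n, p))
    labels = np.array([1] * n + [2] * n)
    if shift is not None:
        x[:n] += shift
    return _matrix(x, labels)


class TestFDR:
    def test_identical_distributions_score_zero(self):
        col = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])[:, None]
        m = _matrix(col, [1, 1, 1, 2, 2, 2])
        assert fdr_scores(m).scores[0] == 0.0

    def test_closed_form(self):
        # m1=1, m2=0, var1=var2=0.5 -> (1-0)^2 / (0.5+0.5) = 1
        c1 = np.array([1 - np.sqrt(0.5), 1 + np.sqrt(0.5)])
        c2 = np.array([-np.sqrt(0.5), np.sqrt(0.5)])
        m = _matrix(np.r_[c1, c2][:, None], [1, 1, 2, 2])
        assert fdr_scores(m).scores[0] == pytest.approx(1.0)

    def test_affine_invariance_of_canonical(self, rng):
        m = _two_class(rng, shift=0.8)
        base = fdr_scores(m).scores
        scaled = _matrix(3.7 * m.values - 11.0, m.labels)
        assert np.allclose(fdr_scores(scaled).scores, base, rtol=1e-9)

    def test_as_printed_variant_differs(self, rng):
        m = _two_class(rng, shift=0.8)
        canonical = fdr_scores(m, "canonical").scores
        printed = fdr_scores(m, "as_printed").scores
        assert not np.allclose(canonical, printed)

    def test_zero_variance_flagged(self):
        col = np.array([1.0, 1.0, 0.0, 0.0])[:, None]
        m = _matrix(col, [1, 1, 2, 2])
        s = fdr_scores(m)
        assert s.floored[0]
        assert s.scores[0] > 1e10

    def test_single_class_rejected(self):
        m = _matrix(np.ones((4, 2)), [1, 1, 1, 1])
        with pytest.raises(ValueError):
            fdr_scores(m)


class TestSelectAboveMedian:
    def _scores(self, values):
        m = _matrix(np.zeros((4, len(values))), [1, 1, 2, 2])
        s = fdr_scores(m)
        s.scores = np.asarray(values, float)
        return s

    def test_even_count_keeps_half(self):
        s = self._scores(np.arange(128.0))
        kept = select_above_median(s)
        assert kept.size == 64
        assert set(kept) == set(range(64, 128))

    def test_odd_count_keeps_ceil(self):
        kept = select_above_median(self._scores([5.0, 1.0, 4.0, 2.0, 3.0]))
        assert kept.size == 3
        assert set(kept) == {0, 2, 4}

    def test_tie_break_by_index(self):
        kept = select_above_median(self._scores([1.0, 1.0, 1.0, 1.0, 1.0]))
        assert kept.tolist() == [0, 1, 2]

    def test_rank_only_dependence(self, rng):
        vals = rng.uniform(1, 2, size=9)
        a = select_above_median(self._scores(vals))
        b = select_above_median(self._scores(np.log(vals)))  # monotone map
        assert a.tolist() == b.tolist()


class TestPCA:
    def test_orthonormal_components(self, rng):
        m = _two_class(rng, n=50, p=8)
        model = pca_fit(m, 0.95)
        eye = model.components.T @ model.components
        assert np.abs(eye - np.eye(model.m)).max() < 1e-9

    def test_rank_one_data(self, rng):
        t = rng.normal(size=30)
        direction = np.array([1.0, -2.0, 0.5, 3.0, 1.5])
        m = _matrix(np.outer(t, direction), [1, 2] * 15)
        model = pca_fit(m, 0.95)
        assert model.m == 1
        assert model.variance_captured == pytest.approx(1.0)

    def test_isotropic_spectrum_retention(self, rng):
        # independent unit-variance features: eigenvalues are near-equal so
        # the 95% rule keeps about ceil(0.95 * p) components
        p = 20
        m = _matrix(rng.normal(size=(20000, p)), [1, 2] * 10000)
        model = pca_fit(m, 0.95)
        assert abs(model.m - int(np.ceil(0.95 * p))) <= 1

    def test_minimal_m(self, rng):
        m = _two_class(rng, n=50, p=8)
        model = pca_fit(m, 0.95)
        frac = np.cumsum(model.eigenvalues) / model.eigenvalues.sum()
        assert frac[model.m - 1] >= 0.95 - 1e-12
        if model.m > 1:
            assert frac[model.m - 2] < 0.95

    def test_transform_of_mean_is_zero(self, rng):
        m = _two_class(rng, n=30, p=5)
        model = pca_fit(m, 0.95)
        mean_row = _matrix(m.values.mean(axis=0, keepdims=True), [1])
        y = pca_transform(model, mean_row)
        assert np.abs(y.values).max() < 1e-9

    def test_full_retention_backprojects_exactly(self, rng):
        m = _two_class(rng, n=30, p=5)
        model = pca_fit(m, 1.0)
        y = pca_transform(model, m)
        back = y.values @ model.components.T + model.center
        assert np.abs(back - m.values).max() < 1e-9

    def test_truncation_error_equals_discarded_eigenvalues(self, rng):
        # on Gaussian data the mean squared back-projection error matches
        # the discarded eigenvalue total
        p = 6
        scales = np.array([3.0, 2.0, 1.0, 0.5, 0.2, 0.1])
        x = rng.normal(size=(20000, p)) * scales
        m = _matrix(x, [1, 2] * 10000)
        model = pca_fit(m, 0.90)
        y = pca_transform(model, m)
        back = y.values @ model.components.T + model.center
        per_instance = ((back - m.values) ** 2).sum(axis=1)
        discarded = model.eigenvalues[model.m :].sum()
        assert per_instance.mean() == pytest.approx(discarded, rel=0.05)

    def test_rank_zero_rejected(self):
        m = _matrix(np.ones((5, 3)), [1, 1, 2, 2, 1])
        with pytest.raises(ValueError, match="rank-0"):
            pca_fit(m)


class TestSelectFeatures:
    def test_composition_keeps_half_then_pca(self, rng):
        m = _two_class(rng, n=60, p=128, shift=rng.normal(scale=0.3, size=128))
        res = select_features(m)
        assert res.kept_feature_indices.size == 64
        assert res.pca.components.shape[0] == 64
        assert res.transformed.values.shape == (120, res.pca.m)

    def test_informative_feature_kept(self, rng):
        n, p = 50, 9
        x = np.tile(rng.normal(size=(2 * n, 1)), (1, p))  # identical noise cols
        x[:, 4] = np.r_[rng.normal(3.0, 1.0, n), rng.normal(-3.0, 1.0, n)]
        m = _matrix(x, [1] * n + [2] * n)
        res = select_features(m)
        assert 4 in res.kept_feature_indices

    def test_full_variance_target_keeps_rank(self, rng):
        m = _two_class(rng, n=30, p=10, shift=0.5)
        res = select_features(m, variance_target=1.0)
        assert res.pca.m == np.linalg.matrix_rank(
            m.values[:, res.kept_feature_indices]
            - m.values[:, res.kept_feature_indices].mean(0)
        )

    def test_deterministic(self, rng):
        m = _two_class(rng, n=40, p=12, shift=0.4)
        r1 = select_features(m)
        r2 = select_features(m)
        assert np.array_equal(r1.kept_feature_indices, r2.kept_feature_indices)
        assert np.array_equal(r1.transformed.values, r2.transformed.values)

    def test_transformed_columns_uncorrelated(self, rng):
        m = _two_class(rng, n=60, p=16, shift=0.3)
        y = select_features(m).transformed.values
        if y.shape[1] > 1:
            corr = np.corrcoef(y, rowvar=False)
            off = corr - np.diag(np.diag(corr))
            assert np.abs(off).max() < 1e-6

    def test_transform_new_data_matches_train_path(self, rng):
        m = _two_class(rng, n=40, p=10, shift=0.5)
        res = select_features(m)
        again = res.transform(m)
        assert np.abs(again.values - res.transformed.values).max() < 1e-9
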