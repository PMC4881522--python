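import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pcafe import (
    ExpressionMatrix,
    bh_adjust,
    chi2_outlier_pvalues,
    decompose,
    normalize_samples,
    select_features,
    select_pcs,
)
from pcafe.pca_fe import (
    NoDiscriminativeComponentsError,
    PCADecomposition,
    PCSelection,
    chi2_outlier_statistic,
)
from pcafe.data_io import CASE, CONTROL
from conftest import labelled_matrix


def dense_gram_eig(X):
    """Brute-force oracle: dense eigendecomposition of the gram matrix XX^T."""
    lam, U = np.linalg.eigh(X @ X.T)
    order = np.argsort(lam)[::-1]
    return lam[order], U[:, order]


def fake_decomposition(scores, sigma=None):
    scores = np.asarray(scores, dtype=float)
    k, n = scores.shape
    if sigma is None:
        sigma = scores.std(axis=1, ddof=1)
    return PCADecomposition(
        scores=scores,
        loadings=np.zeros((k, 2)),
        eigenvalues=np.arange(k, 0, -1, dtype=float),
        sigma=np.asarray(sigma, dtype=float),
    )


class TestDecompose:
    def test_identity_matrix_degenerate_eigenvalues(self):
        m = ExpressionMatrix(np.eye(2), ["A", "B"], ["S1", "S2"])
        d = decompose(m)
        np.testing.assert_allclose(d.eigenvalues, [1.0, 1.0])
        # invariants, not particular vectors: orthonormal scores
        np.testing.assert_allclose(d.scores @ d.scores.T, np.eye(2), atol=1e-12)

    @pytest.mark.parametrize("shape", [(8, 5), (50, 12), (200, 30)])
    def test_matches_dense_gram_oracle(self, shape, rng):
        m = normalize_samples(
            labelled_matrix(rng.normal(size=shape), shape[1] // 2,
                            shape[1] - shape[1] // 2)
        )
        d = decompose(m)
        lam, U = dense_gram_eig(m.values)
        np.testing.assert_allclose(d.eigenvalues, lam[: d.n_components], atol=1e-8)
        for k in range(d.n_components):
            # score subspace agreement up to sign
            assert abs(float(d.scores[k] @ U[:, k])) == pytest.approx(1.0, abs=1e-8)

    def test_eigenvector_identities(self, normalized_matrix):
        d = decompose(normalized_matrix)
        X = normalized_matrix.values
        for k in range(d.n_components):
            u, lam = d.scores[k], d.eigenvalues[k]
            np.testing.assert_allclose(X @ (X.T @ u), lam * u, rtol=1e-8, atol=1e-8)
            np.testing.assert_allclose(d.loadings[k], X.T @ u, atol=1e-10)
            assert np.linalg.norm(u) == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(d.eigenvalues) <= 1e-12)
        assert d.n_components <= min(normalized_matrix.n_features,
                                     normalized_matrix.n_samples)

    def test_sigma_matches_recomputation(self, normalized_matrix):
        d = decompose(normalized_matrix)
        np.testing.assert_allclose(
            d.sigma, d.scores.std(axis=1, ddof=1), atol=1e-12
        )

    def test_single_sample_rejected(self):
        m = ExpressionMatrix(np.ones((3, 1)), ["A", "B", "C"], ["S1"])
        with pytest.raises(ValueError, match="2 samples"):
            decompose(m)


class TestSelectPCs:
    def test_perfectly_separating_component_enters_omega(self, rng):
        loadings = np.vstack(
            [
                np.r_[np.full(10, 1.0), np.full(10, -1.0)] + rng.normal(0, 1e-3, 20),
                rng.normal(size=20),
            ]
        )
        d = PCADecomposition(
            scores=np.zeros((2, 5)),
            loadings=loadings,
            eigenvalues=np.array([2.0, 1.0]),
            sigma=np.ones(2),
        )
        labels = np.array([CASE] * 10 + [CONTROL] * 10, dtype=object)
        assert 0 in select_pcs(d, labels).omega

    def test_null_type_i_error_near_alpha(self, rng):
        k = 200
        d = PCADecomposition(
            scores=np.zeros((k, 5)),
            loadings=rng.normal(size=(k, 30)),
            eigenvalues=np.arange(k, 0, -1, dtype=float),
            sigma=np.ones(k),
        )
        labels = rng.permutation(
            np.array([CASE] * 15 + [CONTROL] * 15, dtype=object)
        )
        frac = len(select_pcs(d, labels, alpha=0.05).omega) / k
        sigma3 = 3 * np.sqrt(0.05 * 0.95 / k)
        assert abs(frac - 0.05) <= sigma3

    def test_pvalue_matches_welch_formula(self):
        x = np.array([1.2, -0.3, 0.7])
        y = np.array([2.5, 3.1, 1.9])
        d = PCADecomposition(
            scores=np.zeros((1, 4)),
            loadings=np.r_[x, y][None, :],
            eigenvalues=np.array([1.0]),
            sigma=np.ones(1),
        )
        labels = np.array([CASE] * 3 + [CONTROL] * 3, dtype=object)
        sel = select_pcs(d, labels)
        # textbook Welch statistic and Welch-Satterthwaite df
        vx, vy = x.var(ddof=1) / 3, y.var(ddof=1) / 3
        t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx**2 / 2 + vy**2 / 2)
        expected = 2 * stats.t.sf(abs(t), df)
        assert sel.pvalues[0] == pytest.approx(expected, rel=1e-12)

    def test_single_class_rejected(self, normalized_matrix):
        d = decompose(normalized_matrix)
        labels = np.array([CASE] * 20, dtype=object)
        with pytest.raises(ValueError, match="both classes"):
            select_pcs(d, labels)


class TestChi2OutlierPvalues:
    def test_zero_scores_give_p_one(self):
        d = fake_decomposition(np.zeros((2, 6)), sigma=np.ones(2))
        sel = PCSelection(omega=[0, 1], pvalues=np.zeros(2))
        np.testing.assert_array_equal(chi2_outlier_pvalues(d, sel), np.ones(6))

    def test_single_component_at_196_sigma(self):
        d = fake_decomposition(np.array([[1.96]]), sigma=np.array([1.0]))
        sel = PCSelection(omega=[0], pvalues=np.zeros(1))
        assert chi2_outlier_pvalues(d, sel)[0] == pytest.approx(0.050, abs=5e-4)

    def test_empty_omega_is_an_error(self):
        d = fake_decomposition(np.ones((1, 3)))
        with pytest.raises(NoDiscriminativeComponentsError, match="no discriminative"):
            chi2_outlier_pvalues(d, PCSelection(omega=[], pvalues=np.ones(1)))

    def test_null_scores_yield_uniform_pvalues(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=(3, 10_000))
        sel = PCSelection(omega=[0, 1, 2], pvalues=np.zeros(3))
        p = chi2_outlier_pvalues(fake_decomposition(scores), sel)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_monotone_in_statistic(self, normalized_matrix):
        d = decompose(normalized_matrix)
        sel = PCSelection(omega=[0, 1], pvalues=np.zeros(2))
        t = chi2_outlier_statistic(d, sel)
        p = chi2_outlier_pvalues(d, sel)
        order = np.argsort(t)
        assert np.all(np.diff(p[order]) <= 1e-15)


class TestBHAdjust:
    def test_closed_form(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03]
        )

    def test_all_ones_stay_capped(self):
        np.testing.assert_array_equal(bh_adjust(np.ones(5)), np.ones(5))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_literal_step_up_definition(self, seed):
        p = np.random.default_rng(seed).uniform(size=200)
        # independent literal coding of the BH step-up definition
        order = np.argsort(p)
        m = len(p)
        scaled = p[order] * m / np.arange(1, m + 1)
        expected_sorted = np.minimum(
            1.0, [min(scaled[r:]) for r in range(m)]
        )
        expected = np.empty(m)
        expected[order] = expected_sorted
        np.testing.assert_allclose(bh_adjust(p), expected, rtol=1e-12)
        assert np.all(bh_adjust(p) >= p - 1e-15)


class TestSelectFeatures:
    def test_sign_flip_and_rescaling_invariance(self, rng):
        values = rng.normal(size=(80, 16))
        values[:5, :8] += 2.0  # ensure a class-contrasted component exists
        m = normalize_samples(labelled_matrix(values, 8, 8))
        fe = select_features(m, threshold=0.5)
        d = fe.decomposition
        flipped = PCADecomposition(
            scores=-d.scores, loadings=-d.loadings,
            eigenvalues=d.eigenvalues, sigma=d.sigma,
        )
        scaled = PCADecomposition(
            scores=3.0 * d.scores, loadings=d.loadings,
            eigenvalues=d.eigenvalues, sigma=3.0 * d.sigma,
        )
        for variant in (flipped, scaled):
            sel = select_pcs(variant, m.labels) if variant is flipped else fe.selection
            p = chi2_outlier_pvalues(variant, sel)
            np.testing.assert_allclose(p, fe.raw_p, rtol=1e-9)
            assert sel.omega == fe.selection.omega or variant is scaled

    def test_planted_shift_features_are_selected(self, rng):
        values = rng.normal(size=(500, 40))
        # planted class shifts in the 20 case samples, both directions
        values[:10, :20] += 3.0
        values[10:20, :20] -= 3.0
        m = normalize_samples(labelled_matrix(values, 20, 20))
        fe = select_features(m)
        planted = set(m.feature_ids[:20])
        hits = planted & set(fe.selected_ids)
        assert len(hits) >= 18
        assert len(set(fe.selected_ids) - planted) <= 2
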