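"""Mixture fitting, AIC model selection, and hyperellipse membership."""

import numpy as np
import pytest
from scipy import stats

import foodlex as fl
from foodlex.clustering import (
    COV_TYPES,
    calibrate,
    count_params,
    em_log_likelihood_trace,
    fit_gmm,
    membership,
    membership_matrix,
)


@pytest.mark.parametrize(
    "K,d,cov_type,expected",
    [
        (1, 1, "spherical", 2),
        (2, 3, "full", 19),
        (3, 2, "tied", 11),
        (2, 4, "diag", 17),
        (4, 5, "spherical", 27),
    ],
)
def test_count_params_formula(K, d, cov_type, expected):
    assert count_params(K, d, cov_type) == expected


@pytest.mark.parametrize("cov_type", COV_TYPES)
def test_count_params_matches_sklearn(cov_type):
    """Cross-check against sklearn's internal parameter count."""
    rng = np.random.default_rng(0)
    X = rng.standard_normal((50, 4))
    m = fit_gmm(X, K=3, cov_type=cov_type, seed=0)
    assert m.n_params == m._gm._n_parameters()


def _two_blobs(n_per=60, d=5, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n_per, d))
    b = rng.standard_normal((n_per, d))
    b[:, 0] += sep
    X = np.vstack([a, b])
    labels = np.array([0] * n_per + [1] * n_per)
    return X, labels


class TestFitGmm:
    def test_k1_is_sample_gaussian(self):
        """One component: MLE mean is the sample mean, weight is one."""
        rng = np.random.default_rng(1)
        X = rng.standard_normal((200, 3)) + [2.0, -1.0, 0.5]
        for ct in COV_TYPES:
            m = fit_gmm(X, K=1, cov_type=ct, seed=1)
            assert m.weights == pytest.approx([1.0])
            np.testing.assert_allclose(m.means[0], X.mean(axis=0), atol=1e-8)

    def test_planted_two_clusters_recovered(self):
        X, labels = _two_blobs()
        m = fit_gmm(X, K=2, cov_type="full", seed=0)
        hard = m.responsibilities(X).argmax(axis=1)
        agreement = max(np.mean(hard == labels), np.mean(hard == 1 - labels))
        assert agreement == 1.0

    @pytest.mark.parametrize("cov_type", COV_TYPES)
    def test_log_likelihood_equals_direct_density(self, cov_type):
        """Reported LL equals Σ_rows log Σ_k π_k N(x; μ_k, Σ_k) via scipy."""
        X, _ = _two_blobs(n_per=40)
        m = fit_gmm(X, K=2, cov_type=cov_type, seed=0)
        dens = np.zeros(len(X))
        for k in range(m.K):
            if cov_type == "full":
                cov = m.covariances[k]
            elif cov_type == "tied":
                cov = m.covariances
            elif cov_type == "diag":
                cov = np.diag(m.covariances[k])
            else:
                cov = m.covariances[k] * np.eye(m.d)
            dens += m.weights[k] * stats.multivariate_normal.pdf(X, m.means[k], cov)
        assert m.log_likelihood == pytest.approx(float(np.sum(np.log(dens))), rel=1e-9)

    def test_aic_identity(self):
        X, _ = _two_blobs()
        m = fit_gmm(X, K=2, cov_type="diag", seed=0)
        assert m.aic == pytest.approx(2 * m.n_params - 2 * m.log_likelihood)
        assert m.aic == pytest.approx(m._gm.aic(X))

    def test_k1_spherical_aic_closed_form(self):
        """AIC for a single spherical Gaussian from the closed-form MLE."""
        rng = np.random.default_rng(5)
        X = rng.standard_normal((150, 3)) * 2.0 + 1.0
        m = fit_gmm(X, K=1, cov_type="spherical", seed=0, reg_covar=0.0)
        n, d = X.shape
        var = float(np.mean((X - X.mean(axis=0)) ** 2))  # pooled MLE variance
        ll = -0.5 * n * d * (np.log(2 * np.pi * var) + 1.0)
        npar = count_params(1, d, "spherical")
        assert m.log_likelihood == pytest.approx(ll, abs=1e-6)
        assert m.aic == pytest.approx(2 * npar - 2 * ll, abs=1e-6)

    def test_n_le_k_rejected(self):
        with pytest.raises(ValueError):
            fit_gmm(np.zeros((3, 2)), K=3, seed=0)

    def test_deterministic_given_seed(self):
        X, _ = _two_blobs()
        m1 = fit_gmm(X, K=2, cov_type="full", seed=9)
        m2 = fit_gmm(X, K=2, cov_type="full", seed=9)
        np.testing.assert_array_equal(m1.means, m2.means)
        assert m1.aic == m2.aic


def test_em_trace_monotone_nondecreasing():
    """Total log-likelihood never decreases across EM iterations."""
    rng = np.random.default_rng(11)
    X = np.vstack(
        [rng.standard_normal((80, 4)) + off for off in ([0] * 4, [4, 0, 0, 0], [0, 4, 0, 0])]
    )
    for ct in ("full", "diag"):
        trace = em_log_likelihood_trace(X, K=3, cov_type=ct, seed=11, n_steps=25)
        diffs = np.diff(trace)
        assert np.all(diffs >= -1e-7), f"{ct}: decreasing EM trace {diffs.min()}"


class TestCalibrate:
    def test_selects_planted_k5(self):
        spec = fl.SyntheticSpec(
            n_food_clusters=5, words_per_cluster=200, n_background_words=0, d=25, seed=3
        )
        space, _, _ = fl.generate_embedding_space(spec)
        best, table = calibrate(space.vectors, range(1, 11), seed=3)
        assert best.K == 5
        assert len(table) == 10 * len(COV_TYPES)
        assert best.aic == pytest.approx(table["aic"].min())

    def test_selects_k1_for_single_blob(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((400, 6))
        best, _ = calibrate(X, range(1, 6), seed=4)
        assert best.K == 1

    def test_deterministic_table(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((100, 3))
        _, t1 = calibrate(X, [1, 2, 3], ("diag",), seed=8)
        _, t2 = calibrate(X, [1, 2, 3], ("diag",), seed=8)
        assert t1.equals(t2)

    def test_selection_invariant_to_row_shuffle(self):
        spec = fl.SyntheticSpec(
            n_food_clusters=3, words_per_cluster=100, n_background_words=0, d=10, seed=6
        )
        space, _, _ = fl.generate_embedding_space(spec)
        X = space.vectors
        best1, _ = calibrate(X, range(1, 7), ("diag", "spherical"), seed=6)
        rng = np.random.default_rng(0)
        best2, _ = calibrate(
            X[rng.permutation(len(X))], range(1, 7), ("diag", "spherical"), seed=6
        )
        assert best1.K == best2.K

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            calibrate(np.zeros((10, 2)), [], seed=0)


class TestMembership:
    @pytest.fixture(scope="class")
    def model(self):
        X, _ = _two_blobs(n_per=100, d=4, sep=12.0, seed=2)
        return fit_gmm(X, K=2, cov_type="full", seed=2)

    def test_center_accepted_in_quantile_mode_for_any_p(self, model):
        for p in (0.01, 0.5, 0.99):
            accepted, values = membership(model, model.means[0], p, mode="quantile")
            assert accepted[0]
            assert values[0] == pytest.approx(0.0, abs=1e-9)

    def test_responsibilities_sum_to_one(self, model):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((20, 4)) * 5
        _, values = membership_matrix(model, X, 0.5, mode="posterior")
        np.testing.assert_allclose(values.sum(axis=1), 1.0, atol=1e-9)

    @pytest.mark.parametrize("cov_type", COV_TYPES)
    def test_quantile_coverage_matches_p(self, cov_type):
        """The p-mass ellipsoid captures ≈ p of the component's own draws."""
        X, _ = _two_blobs(n_per=500, d=4, sep=15.0, seed=13)
        m = fit_gmm(X, K=2, cov_type=cov_type, seed=13)
        p = 0.75
        rng = np.random.default_rng(13)
        k = 0
        if cov_type == "full":
            cov = m.covariances[k]
        elif cov_type == "tied":
            cov = m.covariances
        elif cov_type == "diag":
            cov = np.diag(m.covariances[k])
        else:
            cov = m.covariances[k] * np.eye(m.d)
        draws = rng.multivariate_normal(m.means[k], cov, size=10_000)
        accepted, _ = membership_matrix(m, draws, p, mode="quantile")
        frac = accepted[:, k].mean()
        se = np.sqrt(p * (1 - p) / 10_000)
        assert abs(frac - p) <= 3 * se

    def test_dimension_mismatch_rejected(self, model):
        with pytest.raises(ValueError):
            membership(model, np.zeros(7), 0.5)

    def test_bad_p_rejected(self, model):
        for p in (0.0, 1.0, -0.5):
            with pytest.raises(ValueError):
                membership(model, model.means[0], p)
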