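"""EM training of the background mixture, posteriors and MAP mean adaptation."""

import math

import numpy as np
import pytest

from specgmm.ubm_gmm import (
    GMMParams,
    fit_ubm,
    load_gmm,
    map_adapt_means,
    posteriors,
    save_gmm,
)


def two_cluster_data(rng, n=2000, d=4, sep=4.0, sigma=0.5):
    mu0 = np.zeros(d)
    mu1 = np.full(d, sep)
    half = n // 2
    X = np.vstack([
        rng.normal(mu0, sigma, size=(half, d)),
        rng.normal(mu1, sigma, size=(n - half, d)),
    ])
    return X, mu0, mu1


class TestFitUbm:
    def test_k1_closed_form(self, rng):
        X = rng.normal(size=(200, 3))
        gmm = fit_ubm(X, K=1, seed=0)
        np.testing.assert_allclose(gmm.means[0], X.mean(axis=0), atol=1e-8)
        np.testing.assert_allclose(gmm.variances[0], X.var(axis=0), rtol=1e-6)
        assert gmm.weights.tolist() == [1.0]

    def test_two_cluster_recovery(self, rng):
        X, mu0, mu1 = two_cluster_data(rng)
        gmm = fit_ubm(X, K=2, seed=0)
        order = np.argsort(gmm.means[:, 0])
        assert np.max(np.abs(gmm.means[order[0]] - mu0)) < 0.05
        assert np.max(np.abs(gmm.means[order[1]] - mu1)) < 0.05
        np.testing.assert_allclose(gmm.weights.sum(), 1.0, atol=1e-9)

    def test_loglik_monotone(self, rng):
        X, _, _ = two_cluster_data(rng, n=600)
        gmm = fit_ubm(X, K=3, seed=1)
        ll = np.array(gmm.log_likelihoods)
        scale = np.maximum(np.abs(ll[:-1]), 1.0)
        assert np.all(np.diff(ll) >= -1e-8 * scale)

    def test_k_exceeds_frames_errors(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            fit_ubm(rng.normal(size=(3, 2)), K=5)

    def test_determinism(self, rng):
        X, _, _ = two_cluster_data(rng, n=400)
        a = fit_ubm(X, K=2, seed=42)
        b = fit_ubm(X, K=2, seed=42)
        assert np.array_equal(a.means, b.means)
        assert np.array_equal(a.weights, b.weights)
        assert np.array_equal(a.variances, b.variances)

    def test_matches_reference_em_loglikelihood(self, rng):
        # independent cross-check: a reference EM on the same data should
        # reach a comparable per-frame log-likelihood
        from sklearn.mixture import GaussianMixture

        X, _, _ = two_cluster_data(rng, n=800)
        ours = fit_ubm(X, K=2, seed=0)
        ref = GaussianMixture(
            n_components=2, covariance_type="diag", n_init=3, random_state=0
        ).fit(X)
        per_frame = ours.log_likelihoods[-1] / X.shape[0]
        assert per_frame == pytest.approx(ref.score(X), rel=1e-3)


class TestPosteriors:
    def test_single_component(self, rng):
        gmm = GMMParams(
            weights=np.array([1.0]),
            means=rng.normal(size=(1, 4)),
            variances=np.ones((1, 4)),
        )
        np.testing.assert_allclose(posteriors(gmm, rng.normal(size=4)), [1.0])

    def test_symmetric_equidistant_frame(self):
        gmm = GMMParams(
            weights=np.array([0.5, 0.5]),
            means=np.array([[0.0, 0.0], [2.0, 2.0]]),
            variances=np.ones((2, 2)),
        )
        np.testing.assert_allclose(
            posteriors(gmm, np.array([1.0, 1.0])), [0.5, 0.5], atol=1e-12
        )

    def test_matches_direct_density_ratio(self):
        # brute-force diagonal-Gaussian density evaluation oracle
        weights = np.array([0.6, 0.4])
        means = np.array([[0.0, 0.0], [2.0, 1.0]])
        variances = np.array([[1.0, 0.5], [2.0, 1.0]])
        frame = np.array([1.0, 0.5])

        def dens(k):
            out = weights[k]
            for d in range(2):
                v = variances[k, d]
                out *= math.exp(-((frame[d] - means[k, d]) ** 2) / (2 * v)) / math.sqrt(
                    2 * math.pi * v
                )
            return out

        expected = np.array([dens(0), dens(1)])
        expected /= expected.sum()
        gmm = GMMParams(weights=weights, means=means, variances=variances)
        np.testing.assert_allclose(posteriors(gmm, frame), expected, atol=1e-9)

    def test_sum_to_one_even_for_extreme_frames(self, rng):
        gmm = GMMParams(
            weights=np.array([0.3, 0.7]),
            means=rng.normal(size=(2, 6)),
            variances=np.full((2, 6), 0.01),
        )
        frame = rng.normal(size=6) + 100.0  # far from both components
        p = posteriors(gmm, frame)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(p >= 0)


class TestMapAdaptation:
    @pytest.fixture
    def ubm(self, rng):
        X, _, _ = two_cluster_data(rng, n=500)
        return fit_ubm(X, K=2, seed=0)

    def test_huge_relevance_recovers_ubm_means(self, ubm, rng):
        frames = rng.normal(size=(30, ubm.D))
        adapted, sv = map_adapt_means(ubm, frames, relevance_r=1e12)
        np.testing.assert_allclose(adapted.means, ubm.means, atol=1e-6)

    def test_zero_relevance_single_frame_k1(self, rng):
        X = rng.normal(size=(100, 3))
        ubm = fit_ubm(X, K=1, seed=0)
        frame = rng.normal(size=(1, 3))
        adapted, sv = map_adapt_means(ubm, frame, relevance_r=0.0)
        np.testing.assert_allclose(adapted.means[0], frame[0], atol=1e-12)

    def test_zero_responsibility_component_unchanged(self):
        # second component is so remote that its responsibility underflows to 0
        ubm = GMMParams(
            weights=np.array([0.5, 0.5]),
            means=np.array([[0.0], [1e6]]),
            variances=np.array([[1.0], [1.0]]),
        )
        frames = np.zeros((5, 1))
        adapted, _ = map_adapt_means(ubm, frames, relevance_r=16.0)
        assert adapted.means[1, 0] == ubm.means[1, 0]

    def test_adapted_mean_interpolates(self, ubm, rng):
        from specgmm.ubm_gmm import log_posteriors

        frames = rng.normal(size=(40, ubm.D)) + 1.0
        adapted, _ = map_adapt_means(ubm, frames, relevance_r=16.0)
        resp = np.exp(log_posteriors(ubm, frames))
        nk = resp.sum(axis=0)
        Ek = (resp.T @ frames) / nk[:, None]
        lo = np.minimum(ubm.means, Ek) - 1e-9
        hi = np.maximum(ubm.means, Ek) + 1e-9
        assert np.all((adapted.means >= lo) & (adapted.means <= hi))

    def test_supervector_shape_and_order(self, ubm, rng):
        frames = rng.normal(size=(10, ubm.D))
        adapted, sv = map_adapt_means(ubm, frames, sequence_id="abc")
        assert sv.vector.shape == (ubm.K * ubm.D,)
        np.testing.assert_allclose(sv.vector[: ubm.D], adapted.means[0])
        assert sv.id == "abc"

    def test_kd_arithmetic(self):
        ubm = GMMParams(
            weights=np.full(5, 0.2),
            means=np.zeros((5, 256)),
            variances=np.ones((5, 256)),
        )
        _, sv = map_adapt_means(ubm, np.zeros((2, 256)))
        assert sv.vector.shape == (1280,)

    def test_no_frames_errors(self, ubm):
        with pytest.raises(ValueError, match="at least one frame"):
            map_adapt_means(ubm, np.empty((0, ubm.D)))


class TestSerialization:
    def test_round_trip(self, tmp_path, rng):
        X, _, _ = two_cluster_data(rng, n=300)
        gmm = fit_ubm(X, K=2, seed=5)
        save_gmm(gmm, tmp_path / "ubm.json", config={"K": 2})
        back = load_gmm(tmp_path / "ubm.json")
        np.testing.assert_array_equal(back.means, gmm.means)
        np.testing.assert_array_equal(back.weights, gmm.weights)
        np.testing.assert_array_equal(back.variances, gmm.variances)
        assert back.seed == gmm.seed
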