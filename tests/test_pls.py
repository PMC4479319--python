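"""NIPALS PLS1 against closed-form and alternative-algorithm oracles,
segmented cross-validation, factor selection and Martens' uncertainty test."""

import numpy as np
import pytest

import strawsugar as ss
from strawsugar.pls import CVResult, make_segments

from .oracles import loo_rmse_path, ols_coefficients, svd_pls1


def _random_problem(rng, n=20, p=8, F_true=3, noise=0.05):
    T = rng.normal(size=(n, F_true))
    X = T @ rng.normal(size=(F_true, p)) + 0.1 * rng.normal(size=(n, p))
    y = T @ rng.normal(size=F_true) + noise * rng.normal(size=n)
    return X, y


class TestFitPls1:
    def test_single_informative_column(self):
        rng = np.random.default_rng(0)
        X = np.zeros((30, 6))
        X[:, 2] = rng.normal(size=30)
        X[:, [0, 1, 3, 4, 5]] = 1.0  # constant elsewhere
        y = 3.0 * X[:, 2]
        m = ss.fit_pls1(X, y, 1)
        yhat = ss.predict(m, X)
        assert ss.r_squared(y, yhat) > 1 - 1e-12
        b = m.b_full
        assert abs(b[2]) > 1e-3
        assert np.max(np.abs(np.delete(b, 2))) < 1e-10

    def test_equals_ols_at_full_rank(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            X, y = _random_problem(rng, n=25, p=6, F_true=6, noise=0.2)
            m = ss.fit_pls1(X, y, 6)
            np.testing.assert_allclose(m.b, ols_coefficients(X, y), atol=1e-8)

    @pytest.mark.parametrize("F", [1, 2, 4, 8])
    def test_matches_svd_oracle(self, F):
        rng = np.random.default_rng(2)
        X, y = _random_problem(rng)
        m = ss.fit_pls1(X, y, F)
        pred_fn, b_oracle = svd_pls1(X, y, F)
        np.testing.assert_allclose(ss.predict(m, X), pred_fn(X), atol=1e-8)
        np.testing.assert_allclose(m.b, b_oracle, atol=1e-8)

    def test_matches_sklearn_cross_check(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(3)
        X, y = _random_problem(rng)
        for F in (1, 3, 5):
            m = ss.fit_pls1(X, y, F)
            ref = sklearn.PLSRegression(n_components=F, scale=False).fit(X, y)
            np.testing.assert_allclose(ss.predict(m, X),
                                       ref.predict(X).ravel(), atol=1e-8)

    def test_b_reproduces_predictions_contract(self):
        rng = np.random.default_rng(4)
        X, y = _random_problem(rng)
        m = ss.fit_pls1(X, y, 3)
        manual = m.y_mean + (X - m.x_mean) @ m.b
        np.testing.assert_allclose(ss.predict(m, X), manual)

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(5)
        X, y = _random_problem(rng, n=40, p=12, F_true=5)
        m = ss.fit_pls1(X, y, 5)
        T = (X[:, m.selected] - m.x_mean) @ m.rotation()
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(G))

    def test_y_shift_and_scale_equivariance(self):
        rng = np.random.default_rng(6)
        X, y = _random_problem(rng)
        base = ss.predict(ss.fit_pls1(X, y, 3), X)
        shifted = ss.predict(ss.fit_pls1(X, y + 5.0, 3), X)
        scaled = ss.predict(ss.fit_pls1(X, 2.5 * y, 3), X)
        np.testing.assert_allclose(shifted, base + 5.0, atol=1e-9)
        np.testing.assert_allclose(scaled, 2.5 * base, atol=1e-9)

    def test_zero_variance_y_rejected(self):
        X = np.random.default_rng(7).normal(size=(10, 3))
        with pytest.raises(ValueError, match="variance"):
            ss.fit_pls1(X, np.ones(10), 1)

    def test_too_many_factors_rejected(self):
        rng = np.random.default_rng(8)
        X, y = _random_problem(rng, n=5, p=8)
        with pytest.raises(ValueError, match="F="):
            ss.fit_pls1(X, y, 5)

    def test_predict_on_training_mean_returns_y_mean(self):
        rng = np.random.default_rng(9)
        X, y = _random_problem(rng)
        m = ss.fit_pls1(X, y, 2)
        got = ss.predict(m, X.mean(axis=0, keepdims=True))
        assert got[0] == pytest.approx(y.mean(), abs=1e-10)


class TestSegmentedCV:
    def test_every_sample_predicted_once(self):
        rng = np.random.default_rng(10)
        X, y = _random_problem(rng, n=53)
        cv = ss.segmented_cv(X, y, n_segments=10, max_F=4, seed=0)
        counts = np.bincount(cv.segment_of)
        assert counts.sum() == 53 and counts.max() - counts.min() <= 1
        assert np.all(np.isfinite(cv.predictions))

    def test_bit_reproducible_with_seed(self):
        rng = np.random.default_rng(11)
        X, y = _random_problem(rng, n=60)
        a = ss.segmented_cv(X, y, 10, 5, seed=33)
        b = ss.segmented_cv(X, y, 10, 5, seed=33)
        np.testing.assert_array_equal(a.segment_of, b.segment_of)
        np.testing.assert_array_equal(a.predictions, b.predictions)

    def test_loo_equals_bruteforce_oracle(self):
        rng = np.random.default_rng(12)
        X, y = _random_problem(rng, n=15, p=5)
        cv = ss.segmented_cv(X, y, n_segments=15, max_F=3, seed=0)
        np.testing.assert_allclose(cv.rmsecv, loo_rmse_path(X, y, 3),
                                   atol=1e-8)

    def test_latent_dimension_recovered(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            X, y = _random_problem(rng, n=200, p=20, F_true=3, noise=0.05)
            cv = ss.segmented_cv(X, y, n_segments=10, max_F=8, seed=seed)
            if ss.select_factors(cv) in (2, 3, 4):
                hits += 1
        assert hits >= 45

    def test_pure_noise_selects_few_factors(self):
        small = 0
        for seed in range(50):
            rng = np.random.default_rng(2000 + seed)
            X = rng.normal(size=(60, 15))
            y = rng.normal(size=60)
            cv = ss.segmented_cv(X, y, n_segments=10, max_F=8, seed=seed)
            # overfit grows RMSECV: late factors should not beat early ones
            if ss.select_factors(cv) <= 3:
                small += 1
        assert small >= 40

    def test_max_f_guard(self):
        rng = np.random.default_rng(13)
        X, y = _random_problem(rng, n=12)
        with pytest.raises(ValueError, match="max_F"):
            ss.segmented_cv(X, y, n_segments=4, max_F=10, seed=0)


class TestSelectFactors:
    def _cv(self, rmsecv):
        r = np.asarray(rmsecv, dtype=float)
        return CVResult(rmsecv=r, r2cv=1 - r, predictions=np.empty((0, r.size)),
                        segment_of=np.empty(0, dtype=int),
                        segment_coefs=np.empty((0, 0, r.size)))

    def test_strictly_decreasing_takes_max(self):
        assert ss.select_factors(self._cv([5, 4, 3, 2, 1])) == 5

    def test_flat_takes_one(self):
        assert ss.select_factors(self._cv([2, 2, 2, 2])) == 1

    def test_parsimony_rule_hand_case(self):
        assert ss.select_factors(self._cv([5, 3, 2.0, 1.99, 1.99]),
                                 tol=0.02) == 3


class TestMartens:
    def _cv_and_data(self, seed=0, n=200, p_info=50, p_noise=200):
        rng = np.random.default_rng(seed)
        T = rng.normal(size=(n, 3))
        A = rng.normal(size=(3, p_info))
        Xi = T @ A + 0.1 * rng.normal(size=(n, p_info))
        Xn = rng.normal(size=(n, p_noise))
        X = np.hstack([Xi, Xn])
        y = T @ np.array([1.0, -0.7, 0.5]) + 0.05 * rng.normal(size=n)
        return X, y

    def test_zero_variance_nonzero_coefficient_kept(self):
        rng = np.random.default_rng(20)
        X, y = _random_problem(rng, n=40, p=6)
        cv = ss.segmented_cv(X, y, n_segments=8, max_F=3, seed=1)
        fake = CVResult(rmsecv=cv.rmsecv, r2cv=cv.r2cv,
                        predictions=cv.predictions, segment_of=cv.segment_of,
                        segment_coefs=np.tile(
                            ss.fit_pls1(X, y, 3).b_full[None, :, None],
                            (8, 1, 3)))
        keep, _ = ss.martens_uncertainty(X, y, 3, fake)
        assert keep.all()  # s_j = 0 with b_j != 0 for every variable

    def test_power_and_specificity_single_rep(self):
        X, y = self._cv_and_data(seed=99)
        cv = ss.segmented_cv(X, y, n_segments=10, max_F=5, seed=99)
        keep, refit = ss.martens_uncertainty(X, y, 3, cv)
        assert keep[:50].mean() >= 0.8
        assert keep[50:].mean() <= 0.15
        assert refit.F == 3

    def test_refit_does_not_degrade_cv(self):
        X, y = self._cv_and_data(seed=5)
        cv = ss.segmented_cv(X, y, n_segments=10, max_F=5, seed=5)
        F = ss.select_factors(cv)
        keep, refit = ss.martens_uncertainty(X, y, F, cv)
        cv2 = ss.segmented_cv(X, y, segments=cv.segment_of, max_F=refit.F,
                              selected=keep)
        assert cv2.rmsecv[refit.F - 1] <= 1.05 * cv.rmsecv[F - 1]

    def test_all_rejected_advises_alpha(self):
        rng = np.random.default_rng(21)
        X, y = _random_problem(rng, n=40, p=6)
        cv = ss.segmented_cv(X, y, n_segments=8, max_F=3, seed=2)
        coefs = cv.segment_coefs.copy()
        coefs += 1e3 * rng.normal(size=coefs.shape)  # jackknife variance blows up
        noisy = CVResult(rmsecv=cv.rmsecv, r2cv=cv.r2cv,
                         predictions=cv.predictions, segment_of=cv.segment_of,
                         segment_coefs=coefs)
        with pytest.raises(ValueError, match="alpha"):
            ss.martens_uncertainty(X, y, 3, noisy)


def test_make_segments_partition_property():
    seg = make_segments(103, 10, seed=4)
    sizes = np.bincount(seg)
    assert sizes.sum() == 103
    assert sizes.max() - sizes.min() <= 1
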