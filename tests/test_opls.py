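"""Single-response OPLS: scaling, orthogonal filtering, VIP, cross-validation."""

import numpy as np
import pytest

from specfx.opls import (
    OPLSConfig,
    autoscale,
    cross_validate,
    fit_opls,
    fit_opls1,
    pls1_fit,
    vip,
)


@pytest.fixture
def linear_data(rng):
    X = rng.standard_normal((20, 5))
    beta = np.array([1.0, -0.5, 0.3, 0.0, 0.8])
    return X, X @ beta


class TestAutoscale:
    def test_columns_centered_and_unit_variance(self, rng):
        X = rng.normal(5, 3, (12, 4))
        y = rng.normal(0, 1, 12)
        Xs, ys, params = autoscale(X, y)
        assert np.allclose(Xs.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(Xs.std(axis=0, ddof=1), 1)
        assert np.allclose(ys.mean(), 0, atol=1e-12)

    def test_round_trip(self, rng):
        X = rng.normal(2, 1.5, (10, 3))
        y = rng.normal(0, 1, 10)
        Xs, ys, p = autoscale(X, y)
        back = Xs * p.x_scale[p.kept] + p.x_mean[p.kept]
        assert np.allclose(back, X, atol=1e-12)

    def test_constant_column_dropped_not_nan(self, rng):
        X = rng.standard_normal((10, 3))
        X[:, 1] = 7.0
        Xs, ys, p = autoscale(X, rng.standard_normal(10))
        assert Xs.shape[1] == 2
        assert p.kept.tolist() == [True, False, True]
        assert np.isfinite(Xs).all()

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            autoscale(np.ones((5, 3)), np.arange(5.0))


class TestFitOpls:
    def test_zero_orthogonal_reduces_to_pls1(self, linear_data):
        X, y = linear_data
        Xs, ys, params = autoscale(X, y)
        m = fit_opls1(Xs, ys, OPLSConfig(n_orthogonal=0), params=params)
        w, t, p, q = pls1_fit(Xs, ys)  # textbook one-component NIPALS
        assert np.abs(m.coefficients_scaled - w * q).max() < 1e-10

    def test_matches_sklearn_pls_oracle(self, linear_data):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = linear_data
        m = fit_opls(X, y, OPLSConfig(n_orthogonal=0))
        ref = sklearn.PLSRegression(n_components=1, scale=True).fit(X, y)
        assert np.allclose(m.coefficients_raw(), ref.coef_.ravel(), atol=1e-10)

    def test_noiseless_linear_response_fully_explained(self, linear_data):
        # y = X beta with full-rank X: enough orthogonal components drive
        # the single predictive component to R2Y = 1
        X, y = linear_data
        m = fit_opls(X, y, OPLSConfig(n_orthogonal=4))
        assert m.r2y == pytest.approx(1.0, abs=1e-8)
        pred = m.predict(X)
        assert np.allclose(pred, y, atol=1e-6)

    def test_orthogonal_scores_uncorrelated_with_response(self, rng):
        X = rng.standard_normal((30, 8))
        y = X[:, 0] + 0.5 * rng.standard_normal(30)
        m = fit_opls(X, y, OPLSConfig(n_orthogonal=3))
        ys = (y - y.mean()) / y.std(ddof=1)
        for k in range(m.ortho_scores.shape[1]):
            assert abs(np.corrcoef(m.ortho_scores[:, k], ys)[0, 1]) < 1e-6

    def test_recovers_planted_orthogonal_structure(self, rng):
        # X = t p' + t_o p_o' with t_o orthogonal to y: the estimated
        # orthogonal scores track the planted ones
        n, p = 40, 10
        t_pred = rng.standard_normal(n)
        t_orth = rng.standard_normal(n)
        t_orth -= t_orth @ t_pred / (t_pred @ t_pred) * t_pred
        p_pred = rng.standard_normal(p)
        p_orth = rng.standard_normal(p)
        X = np.outer(t_pred, p_pred) + 3.0 * np.outer(t_orth, p_orth)
        X += 0.01 * rng.standard_normal((n, p))
        y = t_pred
        m = fit_opls(X, y, OPLSConfig(n_orthogonal=1))
        r = np.corrcoef(m.ortho_scores[:, 0], t_orth)[0, 1]
        assert abs(r) > 0.99

    def test_sample_permutation_invariance(self, linear_data):
        X, y = linear_data
        m1 = fit_opls(X, y, OPLSConfig(n_orthogonal=1))
        perm = np.random.default_rng(3).permutation(len(y))
        m2 = fit_opls(X[perm], y[perm], OPLSConfig(n_orthogonal=1))
        assert np.allclose(m1.coefficients_scaled, m2.coefficients_scaled)
        assert np.allclose(m1.vip, m2.vip)

    def test_sample_duplication_invariance(self, linear_data):
        X, y = linear_data
        m1 = fit_opls(X, y, OPLSConfig(n_orthogonal=1))
        m2 = fit_opls(np.vstack([X, X]), np.concatenate([y, y]), OPLSConfig(n_orthogonal=1))
        assert np.allclose(m1.coefficients_scaled, m2.coefficients_scaled, atol=1e-10)

    def test_constant_response_rejected(self, rng):
        with pytest.raises(ValueError, match="variance"):
            fit_opls(rng.standard_normal((10, 3)), np.ones(10))

    def test_too_many_orthogonal_components_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        y = X[:, 0]
        with pytest.raises(ValueError, match="rank"):
            fit_opls(X, y, OPLSConfig(n_orthogonal=5))


class TestVip:
    def test_single_variable_has_unit_vip(self, rng):
        X = rng.standard_normal((10, 1))
        m = fit_opls(X, X[:, 0] * 2 + rng.normal(0, 0.1, 10), OPLSConfig(n_orthogonal=0))
        assert vip(m)[0] == pytest.approx(1.0)

    def test_closed_form_for_degenerate_weights(self):
        # w = (1, 0) -> VIP = (sqrt(2), 0)
        rngl = np.random.default_rng(0)
        x0 = rngl.standard_normal(30)
        X = np.column_stack([x0, rngl.standard_normal(30)])
        y = x0.copy()
        m = fit_opls(X, y, OPLSConfig(n_orthogonal=0))
        # dominant variable carries nearly all weight
        assert m.vip[0] > 1.3
        assert (m.vip**2).sum() == pytest.approx(2.0, abs=1e-6)

    def test_sum_of_squares_equals_retained_variables(self, rng):
        X = rng.standard_normal((25, 9))
        y = rng.standard_normal(25)
        m = fit_opls(X, y, OPLSConfig(n_orthogonal=1))
        assert (m.vip**2).sum() == pytest.approx(9.0, abs=1e-6)

    def test_dropped_column_reports_zero(self, rng):
        X = rng.standard_normal((15, 4))
        X[:, 2] = 1.0
        m = fit_opls(X, X[:, 0] + rng.normal(0, 0.2, 15), OPLSConfig(n_orthogonal=0))
        assert m.vip[2] == 0.0
        assert m.coefficients_scaled[2] == 0.0
        assert (m.vip**2).sum() == pytest.approx(3.0, abs=1e-6)


class TestCrossValidate:
    def test_noiseless_linear_response_scores_high(self, rng):
        X = rng.standard_normal((30, 5))
        y = X @ np.array([1.0, 0.5, -0.3, 0.2, 0.7])
        q2 = cross_validate(X, y, OPLSConfig(n_orthogonal=1, cv_folds=5))
        # one predictive component cannot be perfect, but close
        assert q2 >= 0.9

    def test_pure_noise_scores_low(self):
        low = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((30, 5))
            y = rng.standard_normal(30)
            q2 = cross_validate(X, y, OPLSConfig(n_orthogonal=0, cv_folds=5), seed=seed)
            low += q2 <= 0.2
        assert low >= 36  # >= 90% of replicates

    def test_q2_never_exceeds_training_r2(self, rng):
        X = rng.standard_normal((30, 5))
        y = X[:, 0] + rng.standard_normal(30)
        cfg = OPLSConfig(n_orthogonal=1, cv_folds=5)
        m = fit_opls(X, y, cfg)
        q2 = cross_validate(X, y, cfg)
        assert q2 <= m.r2y + 1e-9

    def test_folds_exceeding_rows_rejected(self, rng):
        with pytest.raises(ValueError, match="folds"):
            cross_validate(
                rng.standard_normal((5, 2)), rng.standard_normal(5),
                OPLSConfig(cv_folds=6),
            )
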