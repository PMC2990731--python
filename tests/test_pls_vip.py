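"""NIPALS PLS regression, factor selection and the VIP statistic."""

import warnings

import numpy as np
import pytest

from zbind.pls_vip import (
    PLSModel,
    compute_vip,
    fit_pls,
    predict_pls,
    press_by_factors,
    select_factors,
    vip_table,
)
from .conftest import make_linear_problem


def _fit_quiet(*args, **kwargs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_pls(*args, **kwargs)


def test_perfect_univariate_fit():
    y = np.arange(12, dtype=float)
    m = _fit_quiet(y[:, None], y, 1)
    assert m.coefficients == pytest.approx([1.0], abs=1e-10)
    assert m.ssy[-1] == pytest.approx(0.0, abs=1e-18)


def test_full_rank_pls_equals_ols_oracle():
    rng = np.random.default_rng(42)
    X = rng.normal(size=(12, 4))
    y = X @ np.array([1.0, -2.0, 0.5, 3.0]) + 0.1 * rng.normal(size=12)
    m = _fit_quiet(X, y, 4)
    # independent normal-equations oracle
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    ols = np.linalg.solve(Xc.T @ Xc, Xc.T @ yc)
    np.testing.assert_allclose(m.coefficients, ols, atol=1e-6)


def test_permuted_response_destroys_signal():
    X, y, _ = make_linear_problem(9, n=80, r2=0.9, seed=2)
    rng = np.random.default_rng(0)
    m = fit_pls(X, y, 2)
    mp = fit_pls(X, rng.permutation(y), 2)
    frac = lambda m: (m.ssy[0] - m.ssy[2]) / m.ssy[0]
    assert frac(mp) < frac(m)


def test_agrees_with_sklearn_nipals():
    # independent route: sklearn's NIPALS with centering only (scale=False)
    from sklearn.cross_decomposition import PLSRegression

    X, y, _ = make_linear_problem(9, n=60, r2=0.8, seed=4)
    for a in (1, 2, 3):
        sk = PLSRegression(n_components=a, scale=False).fit(X, y)
        m = fit_pls(X, y, a)
        np.testing.assert_allclose(m.coefficients, sk.coef_.ravel(), atol=1e-8)


class TestFitErrors:
    def test_zero_variance_response(self):
        X = np.random.default_rng(0).normal(size=(40, 3))
        with pytest.raises(ValueError, match="variance"):
            fit_pls(X, np.ones(40), 1)

    def test_factors_beyond_rank(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(40, 2))
        X = np.column_stack([base, base @ rng.normal(size=(2, 2))])  # rank 2
        y = rng.normal(size=40)
        with pytest.raises(ValueError, match="rank"):
            fit_pls(X, y, 3)


class TestPredict:
    @pytest.fixture()
    def model_and_data(self):
        X, y, _ = make_linear_problem(9, n=60, r2=0.85, seed=6)
        return fit_pls(X, y, 2), X, y

    def test_training_consistency(self, model_and_data):
        m, X, y = model_and_data
        fitted = m.y_center + m.scores @ m.y_loadings
        np.testing.assert_allclose(predict_pls(m, X), fitted, atol=1e-8)

    def test_centering_identity(self, model_and_data):
        m, _, _ = model_and_data
        assert predict_pls(m, m.x_center[None, :])[0] == pytest.approx(m.y_center)

    def test_dimension_mismatch(self, model_and_data):
        m, X, _ = model_and_data
        with pytest.raises(ValueError, match="columns"):
            predict_pls(m, X[:, :-1])

    def test_null_coefficient_column_is_inert(self):
        # second column orthogonal to both y and the signal column: its PLS
        # coefficient is 0, so rescaling it cannot move predictions
        rng = np.random.default_rng(3)
        x1 = rng.normal(size=50)
        y = 2.0 * x1 + 0.05 * rng.normal(size=50)
        x2 = rng.normal(size=50)
        for v in (x1, y):
            vc = v - v.mean()
            x2 -= (x2 @ vc) / (vc @ vc) * vc
        X = np.column_stack([x1, x2])
        m = fit_pls(X, y, 1)
        assert m.coefficients[1] == pytest.approx(0.0, abs=1e-10)
        X2 = X.copy()
        X2[:, 1] *= 2.0
        np.testing.assert_allclose(predict_pls(m, X2), predict_pls(m, X), atol=1e-8)


def _latent_problem(n_latent, n=90, K=10, noise=1e-4, seed=0):
    rng = np.random.default_rng(seed)
    T = rng.normal(size=(n, n_latent))
    P = rng.normal(size=(n_latent, K))
    X = T @ P + noise * rng.normal(size=(n, K))
    y = T @ rng.normal(size=n_latent) + noise * rng.normal(size=n)
    return X, y


class TestSelectFactors:
    def test_two_latent_directions(self):
        X, y = _latent_problem(2, seed=1)
        assert select_factors(X, y, max_factors=5, seed=0) == 2

    def test_pure_noise_floors_at_one(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 6))
        y = rng.normal(size=60)
        assert select_factors(X, y, max_factors=5, seed=0) == 1

    def test_three_latent_directions_vs_exhaustive_press(self):
        X, y = _latent_problem(3, seed=7)
        chosen = select_factors(X, y, max_factors=6, n_folds=7, seed=3)
        assert chosen == 3
        # independent oracle: exhaustive PRESS scan with per-(fold, A) refits
        idx = np.random.default_rng(3).permutation(len(y))
        blocks = np.array_split(idx, 7)
        press = np.zeros(6)
        for a in range(1, 7):
            for val in blocks:
                train = np.setdiff1d(idx, val)
                m = fit_pls(X[train], y[train], a)
                press[a - 1] += np.sum((y[val] - predict_pls(m, X[val])) ** 2)
        np.testing.assert_allclose(
            press_by_factors(X, y, 6, n_folds=7, seed=3), press, rtol=1e-8
        )
        within = np.flatnonzero(press <= 1.02 * press.min())
        assert chosen == within[0] + 1


class TestVIP:
    def test_single_dimension_closed_form(self):
        X, y, _ = make_linear_problem(9, n=50, r2=0.9, seed=8)
        m = fit_pls(X, y, 1)
        vip = compute_vip(m)
        # A=1: sum of squared weights is 1, so VIP_k = sqrt(K) |w_k1|
        np.testing.assert_allclose(
            vip.vip_flat, np.sqrt(27) * np.abs(m.weights[:, 0]), atol=1e-10
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_sum_of_squares_normalization(self, seed):
        X, y, _ = make_linear_problem(9, n=40 + 5 * seed, r2=0.8, seed=seed)
        m = fit_pls(X, y, 1 + seed % 3)
        vip = compute_vip(m)
        assert float(np.sum(vip.vip_flat**2)) / 27 == pytest.approx(1.0, abs=1e-6)

    def test_literal_term_by_term_oracle(self):
        # 6-term, 2-factor model checked against a spreadsheet-style
        # evaluation of the VIP formula, one term at a time
        rng = np.random.default_rng(12)
        X = rng.normal(size=(30, 6))
        y = X @ np.array([2.0, -1.0, 0.0, 0.5, 0.0, 1.5]) + 0.2 * rng.normal(size=30)
        m = fit_pls(X, y, 2)
        vip = compute_vip(m)
        K, A = 6, 2
        for k in range(K):
            acc = 0.0
            for a in range(1, A + 1):
                acc += m.weights[k, a - 1] ** 2 * (m.ssy[a - 1] - m.ssy[a])
            expected = np.sqrt(acc * K / (m.ssy[0] - m.ssy[A]))
            assert vip.vip_flat[k] == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_response_shift(self):
        X, y, _ = make_linear_problem(9, n=50, r2=0.9, seed=9)
        a = compute_vip(fit_pls(X, y, 2))
        b = compute_vip(fit_pls(X, y + 100.0, 2))
        np.testing.assert_allclose(a.vip_flat, b.vip_flat, atol=1e-9)

    def test_no_explained_variance_rejected(self):
        X, y, _ = make_linear_problem(9, n=50, r2=0.9, seed=10)
        m = fit_pls(X, y, 1)
        m.ssy = np.array([m.ssy[0], m.ssy[0]])
        with pytest.raises(ValueError, match="VIP"):
            compute_vip(m)

    def test_grid_geometry_and_table_export(self):
        X, y, _ = make_linear_problem(15, n=60, r2=0.9, seed=3)
        vips = []
        for allele in ("DRB1*0101", "DRB3*0101"):
            vips.append(compute_vip(fit_pls(X, y, 2), allele=allele))
        assert vips[0].values.shape == (15, 3)
        df = vip_table(vips)
        assert list(df.index) == ["DRB1*0101", "DRB3*0101"]
        assert df.shape == (2, 45)
        assert df.columns[0] == "N-3:PC1" and df.columns[-1] == "C+3:PC3"


def test_ssy_non_increasing_and_monotone_residuals():
    X, y, _ = make_linear_problem(9, n=70, r2=0.7, seed=13)
    m = fit_pls(X, y, 5)
    assert np.all(np.diff(m.ssy) <= 1e-9)


def test_model_json_roundtrip(tmp_path):
    X, y, _ = make_linear_problem(9, n=40, r2=0.9, seed=14)
    m = fit_pls(X, y, 2)
    p = tmp_path / "model.json"
    m.save(p)
    back = PLSModel.load(p)
    np.testing.assert_array_equal(back.coefficients, m.coefficients)
    np.testing.assert_array_equal(back.ssy, m.ssy)
    assert back.position_labels == m.position_labels
    np.testing.assert_allclose(back.predict(X), m.predict(X))


def test_parameter_recovery_with_selected_factors():
    # y = X beta + noise at population R^2 0.9: the PLS solution with a
    # CV-selected factor count points in the direction of the planted truth
    X, y, beta = make_linear_problem(15, n=500, r2=0.9, seed=11)
    a = select_factors(X, y, max_factors=6, seed=1)
    m = fit_pls(X, y, a)
    cos = float(
        m.coefficients @ beta / np.linalg.norm(m.coefficients) / np.linalg.norm(beta)
    )
    assert cos >= 0.95
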