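import numpy as np
import pytest

from metabosel.multivariate import (
    fit_opls_da,
    fit_pca,
    hotelling_outliers,
    opls_da_on_table,
    opls_predict,
    q2_cv,
    select_by_vip,
    vip,
)
from metabosel.preprocess import apply_scaler, fit_scaler

from conftest import table_from_arrays


# ----------------------------------------------------------------------
# PCA
# ----------------------------------------------------------------------
def _centered(seed, n=30, p=8):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    return X - X.mean(axis=0)


def test_pca_matches_eigendecomposition_oracle():
    X = _centered(0)
    m = fit_pca(X, 4)
    eigvals = np.sort(np.linalg.eigvalsh(np.cov(X, rowvar=False)))[::-1]
    assert np.allclose(m.eigenvalues, eigvals[:4], atol=1e-10)
    assert np.allclose(m.explained_variance, eigvals[:4] / eigvals.sum(), atol=1e-10)
    # loadings orthonormal, scores = X @ loadings
    assert np.allclose(m.loadings.T @ m.loadings, np.eye(4), atol=1e-10)
    assert np.allclose(m.scores, X @ m.loadings, atol=1e-12)
    # explained variance non-increasing
    assert np.all(np.diff(m.explained_variance) <= 1e-12)


def test_pca_rank_one_and_full_reconstruction():
    rng = np.random.default_rng(1)
    X = np.outer(rng.normal(size=20), rng.normal(size=5))
    X -= X.mean(axis=0)
    m = fit_pca(X, 1)
    assert m.explained_variance[0] == pytest.approx(1.0)
    X2 = _centered(2, n=10, p=4)
    full = fit_pca(X2, 4)
    assert np.allclose(full.scores @ full.loadings.T, X2, atol=1e-10)
    with pytest.raises(ValueError):
        fit_pca(X2, 10)


def test_pca_sign_convention_deterministic():
    X = _centered(3)
    m = fit_pca(X, 3)
    for a in range(3):
        v = m.loadings[:, a]
        assert v[np.argmax(np.abs(v))] > 0


# ----------------------------------------------------------------------
# Hotelling's T2
# ----------------------------------------------------------------------
def test_hotelling_centroid_never_flagged_and_sign_invariant():
    X = _centered(4, n=40, p=6)
    X[0] = 0.0  # the centroid sample after centering
    X -= X.mean(axis=0)
    m = fit_pca(X, 2)
    flags = hotelling_outliers(m, 0.95)
    t2 = np.sum(m.scores**2 / m.eigenvalues, axis=1)
    assert t2[np.argmin(np.abs(m.scores).sum(axis=1))] == np.min(t2)
    m.scores = -m.scores
    assert np.array_equal(hotelling_outliers(m, 0.95), flags)


def test_hotelling_flagged_fraction_near_nominal():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(3000, 5))
    X -= X.mean(axis=0)
    m = fit_pca(X, 2)
    frac = hotelling_outliers(m, 0.95).mean()
    assert abs(frac - 0.05) < 0.015  # binomial error at n=3000


def test_hotelling_requires_enough_samples_and_components():
    X = _centered(6, n=10, p=4)
    m = fit_pca(X, 1)
    with pytest.raises(ValueError):
        hotelling_outliers(m)


# ----------------------------------------------------------------------
# OPLS-DA
# ----------------------------------------------------------------------
def _two_group_xy(seed, n=24, p=10, effect=1.5):
    rng = np.random.default_rng(seed)
    y = np.array([1.0] * (n // 2) + [-1.0] * (n // 2))
    X = rng.normal(size=(n, p))
    X[:, 0] += effect * y
    X[:, 1] += 0.5 * effect * y
    Z = apply_scaler(X, fit_scaler(X, "uv"))
    return Z, y


def test_no_orthogonal_components_equals_pls1():
    Z, y = _two_group_xy(0)
    m = fit_opls_da(Z, y, n_orth=0)
    # independent single-component PLS1: w ∝ X'y, t = Xw, c = y't/t't
    w = Z.T @ y
    w /= np.linalg.norm(w)
    t = Z @ w
    sign = np.sign(w[np.argmax(np.abs(w))])
    assert np.allclose(m.t, t * sign, atol=1e-8)
    c = (y @ (t * sign)) / ((t * sign) @ (t * sign))
    assert m.c == pytest.approx(c, abs=1e-10)


def test_orthogonality_invariants():
    Z, y = _two_group_xy(1, n=30, p=15)
    m = fit_opls_da(Z, y, n_orth=3)
    assert np.linalg.norm(m.w) == pytest.approx(1.0)
    for k in range(m.n_orth):
        assert abs(m.w_orth[k] @ m.w) < 1e-10
        for k2 in range(k + 1, m.n_orth):
            corr = m.t_orth[k] @ m.t_orth[k2] / (
                np.linalg.norm(m.t_orth[k]) * np.linalg.norm(m.t_orth[k2])
            )
            assert abs(corr) < 1e-8


def test_osc_deflation_shrinks_frobenius_norm():
    Z, y = _two_group_xy(2, n=30, p=15)
    norms = []
    X = Z.copy()
    m = fit_opls_da(Z, y, n_orth=3)
    for k in range(m.n_orth):
        before = np.linalg.norm(X)
        X = X - np.outer(m.t_orth[k], m.p_orth[k])
        assert np.linalg.norm(X) < before


def test_informative_column_dominates_and_r2y_approaches_one():
    rng = np.random.default_rng(3)
    y = np.array([1.0] * 10 + [-1.0] * 10)
    for noise in (0.5, 0.05):
        X = rng.normal(scale=noise, size=(20, 4))
        X[:, 2] = y + rng.normal(scale=noise, size=20)
        Z = X - X.mean(axis=0)
        m = fit_opls_da(Z, y, n_orth=0)
        assert np.argmax(np.abs(m.w)) == 2
    assert m.r2y > 0.99


def test_error_when_no_predictive_variation():
    y = np.array([1.0, 1.0, -1.0, -1.0])
    X = np.array([[1.0, 2.0], [-1.0, -2.0], [1.0, 2.0], [-1.0, -2.0]])  # X'y = 0
    with pytest.raises(ValueError, match="no predictive variation"):
        fit_opls_da(X, y, n_orth=0)


def test_opls_small_matrix_matches_exact_recursion_oracle():
    """6x3 fit agrees with the same recursion in exact (sympy) arithmetic."""
    sympy = pytest.importorskip("sympy")
    Xint = [[2, -1, 0], [1, 3, -2], [-3, 0, 1], [0, -2, 2], [-1, 1, -1], [1, -1, 0]]
    yint = [1, 1, 1, -1, -1, -1]
    X = sympy.Matrix(Xint)
    y = sympy.Matrix(yint)
    w = X.T * y
    w = w / sympy.sqrt((w.T * w)[0])
    t = X * w
    p_load = X.T * t / (t.T * t)[0]
    w_o = p_load - (w.T * p_load)[0] * w
    w_o = w_o / sympy.sqrt((w_o.T * w_o)[0])
    t_o = X * w_o
    p_o = X.T * t_o / (t_o.T * t_o)[0]
    Xd = X - t_o * p_o.T
    t_final = Xd * w
    c = (y.T * t_final)[0] / (t_final.T * t_final)[0]

    m = fit_opls_da(np.array(Xint, dtype=float), np.array(yint, dtype=float), n_orth=1)

    def aligned(impl, oracle):
        oracle = np.array([float(sympy.N(v, 30)) for v in oracle])
        sign = np.sign(impl @ oracle)
        return impl, sign * oracle

    for impl, oracle in [(m.w, w), (m.t, t_final), (m.w_orth[0], w_o), (m.t_orth[0], t_o)]:
        a, b = aligned(np.asarray(impl), oracle)
        assert np.allclose(a, b, atol=1e-10)
    assert abs(m.c) == pytest.approx(abs(float(sympy.N(c, 30))), abs=1e-10)


# ----------------------------------------------------------------------
# VIP
# ----------------------------------------------------------------------
def test_vip_symmetry_and_concentration():
    m = fit_opls_da(
        np.array([[1.0, 1.0], [2.0, 2.0], [-1.0, -1.0], [-2.0, -2.0]]),
        np.array([1.0, 1.0, -1.0, -1.0]),
        n_orth=0,
    )
    assert np.allclose(vip(m), [1.0, 1.0])
    # all weight on one of 4 features -> VIP = (2, 0, 0, 0)
    rng = np.random.default_rng(0)
    y = np.array([1.0] * 6 + [-1.0] * 6)
    X = np.zeros((12, 4))
    X[:, 0] = y
    m2 = fit_opls_da(X, y, n_orth=0)
    assert np.allclose(vip(m2), [2.0, 0.0, 0.0, 0.0], atol=1e-12)


def test_vip_mean_square_is_one_on_random_models():
    rng = np.random.default_rng(7)
    for _ in range(20):
        n, p = rng.integers(10, 40), rng.integers(3, 60)
        y = np.array([1.0] * (n // 2) + [-1.0] * (n - n // 2))
        X = rng.normal(size=(n, p))
        m = fit_opls_da(X - X.mean(axis=0), y, n_orth=rng.integers(0, 3))
        assert np.mean(vip(m) ** 2) == pytest.approx(1.0, abs=1e-8)


def test_select_by_vip_strict_threshold_and_oracle(filtered_imputed):
    table, _ = filtered_imputed
    m = opls_da_on_table(table, "uv", 1)
    sel = select_by_vip(m, 1.0)
    v = np.sqrt(len(m.feature_ids)) * np.abs(m.w / np.linalg.norm(m.w))
    oracle = {f for f, vv in zip(m.feature_ids, v) if vv > 1.0}
    assert sel == oracle
    assert 0 < len(sel) < len(m.feature_ids)
    # symmetric two-feature case: all VIP exactly 1 -> strict > selects none
    m2 = fit_opls_da(
        np.array([[1.0, 1.0], [2.0, 2.0], [-1.0, -1.0], [-2.0, -2.0]]),
        np.array([1.0, 1.0, -1.0, -1.0]),
        n_orth=0,
    )
    m2.feature_ids = ["x", "y"]
    assert select_by_vip(m2, 1.0) == set()


# ----------------------------------------------------------------------
# Q2 cross-validation
# ----------------------------------------------------------------------
def test_q2_near_one_for_perfectly_predictive_feature():
    rng = np.random.default_rng(8)
    n = 28
    y_num = np.array([1.0] * 14 + [-1.0] * 14)
    # every feature tracks the class difference almost noiselessly
    X = 100 + 10 * y_num[:, None] + rng.normal(0, 0.1, size=(n, 6))
    t = table_from_arrays(X, ["a"] * 14 + ["b"] * 14)
    q2 = q2_cv(t, "uv", n_orth=0, k=7, seed=0)
    assert 0.95 < q2 <= 1.0


def test_q2_nonpositive_on_pure_noise():
    vals = []
    for seed in range(5):
        rng = np.random.default_rng(seed)
        X = rng.lognormal(5, 0.3, size=(60, 20))
        t = table_from_arrays(X, ["a"] * 30 + ["b"] * 30)
        vals.append(q2_cv(t, "uv", n_orth=1, k=7, seed=seed))
    assert np.mean(vals) <= 0
    assert all(v <= 1 for v in vals)


def test_q2_deterministic_given_seed(filtered_imputed):
    table, _ = filtered_imputed
    a = q2_cv(table, "pareto", 1, k=7, seed=123)
    b = q2_cv(table, "pareto", 1, k=7, seed=123)
    assert a == b


def test_q2_rejects_too_many_folds():
    rng = np.random.default_rng(9)
    X = rng.lognormal(5, 0.3, size=(8, 4))
    t = table_from_arrays(X, ["a"] * 4 + ["b"] * 4)
    with pytest.raises(ValueError, match="exceeds"):
        q2_cv(t, "uv", 1, k=7, seed=0)
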