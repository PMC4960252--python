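"""Numba coordinate-descent kernels for L1-penalized logistic regression.

Minimises  g(β) = −ℓ(y, β) + λ Σ_j v_j |β_j|  (no 1/n factor), with ℓ the
Bernoulli log-likelihood, an unpenalized intercept and per-feature penalty
multipliers v_j.  The outer loop is iteratively reweighted least squares
(IRLS): at the current (β₀, β) form the working response
z = η + (y − π)/w with weights w = π(1 − π), then solve the weighted
quadratic by cyclic coordinate descent with soft-thresholding,

    β_j ← S( Σ_i w_i x_ij r_ij , λ v_j ) / Σ_i w_i x_ij²,

where r_ij is the partial residual excluding feature j.  The residual uses
the exact probabilities (so the stationary point satisfies the true KKT
conditions); only the curvature weights w = π(1 − π) are floored at 1e−5,
which bounds the step sizes near separation without biasing the gradient.
"""

import numpy as np
from numba import njit

__all__ = ["fit_path", "fit_single"]

_PMIN = 1e-5


@njit(cache=True)
def _soft(x, thr):
    if x > thr:
        return x - thr
    if x < -thr:
        return x + thr
    return 0.0


@njit(cache=True)
def _objective(X, y, beta, b0, lam, pen):
    n = X.shape[0]
    eta = X @ beta + b0
    nll = 0.0
    for i in range(n):
        # -log-likelihood via log(1 + exp(.)), stable form
        e = eta[i]
        if e > 0:
            nll += e - y[i] * e + np.log1p(np.exp(-e))
        else:
            nll += -y[i] * e + np.log1p(np.exp(e))
    l1 = 0.0
    for j in range(beta.size):
        l1 += pen[j] * abs(beta[j])
    return nll + lam * l1


@njit(cache=True)
def _cd_pass(X, r, w, beta, lam, pen, den, n, p, active_only):
    """One coordinate-descent sweep; returns the largest coefficient change."""
    max_delta = 0.0
    for j in range(p):
        bj = beta[j]
        if active_only and bj == 0.0:
            continue
        if den[j] <= 0.0:
            continue
        num = den[j] * bj
        for i in range(n):
            num += w[i] * X[i, j] * r[i]
        bj_new = _soft(num, lam * pen[j]) / den[j]
        d = bj_new - bj
        if d != 0.0:
            for i in range(n):
                r[i] -= X[i, j] * d
            beta[j] = bj_new
            if abs(d) > max_delta:
                max_delta = abs(d)
    return max_delta


@njit(cache=True)
def _intercept_step(r, w, sw, n):
    swr = 0.0
    for i in range(n):
        swr += w[i] * r[i]
    d0 = swr / sw
    if d0 != 0.0:
        for i in range(n):
            r[i] -= d0
    return d0


@njit(cache=True)
def _fit_one(X, y, lam, pen, beta, b0, tol, max_outer, max_inner, obj_trace):
    """IRLS + coordinate descent at one λ; updates beta/b0 in place.

    Returns (intercept, n_outer, converged_flag); obj_trace[k] holds the
    penalized objective after outer iteration k.
    """
    n, p = X.shape
    converged = False
    n_outer = 0
    prev_obj = _objective(X, y, beta, b0, lam, pen)
    for outer in range(max_outer):
        eta = X @ beta + b0
        pi = 1.0 / (1.0 + np.exp(-eta))
        w = pi * (1.0 - pi)
        for i in range(n):
            if w[i] < _PMIN:
                w[i] = _PMIN
        # working-response residual at the current coefficients, z − η;
        # w r = y − π is the exact score, so CD stationarity = true KKT
        r = (y - pi) / w
        beta_old_outer = beta.copy()
        b0_old_outer = b0
        # weights are fixed within the inner solve, so the per-coordinate
        # curvature Σ w x² is precomputed once per outer iteration
        den = np.empty(p)
        for j in range(p):
            dj = 0.0
            for i in range(n):
                dj += w[i] * X[i, j] * X[i, j]
            den[j] = dj
        sw = 0.0
        for i in range(n):
            sw += w[i]
        # weighted coordinate descent on (X, z, w): alternate full passes with
        # sweeps over the current active set (glmnet-style)
        inner = 0
        while inner < max_inner:
            # full pass
            max_delta = _cd_pass(X, r, w, beta, lam, pen, den, n, p, False)
            sw_d0 = _intercept_step(r, w, sw, n)
            b0 += sw_d0
            if abs(sw_d0) > max_delta:
                max_delta = abs(sw_d0)
            inner += 1
            if max_delta < tol:
                break
            # active-set sweeps until stable
            while inner < max_inner:
                max_delta = _cd_pass(X, r, w, beta, lam, pen, den, n, p, True)
                sw_d0 = _intercept_step(r, w, sw, n)
                b0 += sw_d0
                if abs(sw_d0) > max_delta:
                    max_delta = abs(sw_d0)
                inner += 1
                if max_delta < tol:
                    break
        n_outer = outer + 1
        obj = _objective(X, y, beta, b0, lam, pen)
        # IRLS is not guaranteed monotone in the true penalized objective;
        # halve the step until it is (descent safeguard)
        halvings = 0
        while obj > prev_obj + 1e-12 * (1.0 + abs(prev_obj)) and halvings < 30:
            for j in range(p):
                beta[j] = 0.5 * (beta[j] + beta_old_outer[j])
            b0 = 0.5 * (b0 + b0_old_outer)
            obj = _objective(X, y, beta, b0, lam, pen)
            halvings += 1
        prev_obj = obj
        obj_trace[outer] = obj
        delta_outer = abs(b0 - b0_old_outer)
        for j in range(p):
            dj = abs(beta[j] - beta_old_outer[j])
            if dj > delta_outer:
                delta_outer = dj
        if delta_outer < tol:
            converged = True
            break
    return b0, n_outer, converged


@njit(cache=True)
def fit_path(X, y, lambdas, pen, tol, max_outer, max_inner):
    """Warm-started fits along a decreasing λ grid.

    Returns (betas L×p, intercepts L, n_outer L, converged L).
    """
    L = lambdas.size
    n, p = X.shape
    betas = np.zeros((L, p))
    b0s = np.zeros(L)
    iters = np.zeros(L, dtype=np.int64)
    conv = np.zeros(L, dtype=np.bool_)
    beta = np.zeros(p)
    ybar = y.mean()
    b0 = np.log(ybar / (1.0 - ybar))
    trace = np.zeros(max_outer)
    for l in range(L):
        b0, n_outer, ok = _fit_one(
            X, y, lambdas[l], pen, beta, b0, tol, max_outer, max_inner, trace
        )
        betas[l] = beta
        b0s[l] = b0
        iters[l] = n_outer
        conv[l] = ok
    return betas, b0s, iters, conv


@njit(cache=True)
def fit_single(X, y, lam, pen, beta0, b0_init, tol, max_outer, max_inner):
    """Single-λ fit from a warm start; also returns the objective trace."""
    beta = beta0.copy()
    trace = np.full(max_outer, np.nan)
    b0, n_outer, ok = _fit_one(
        X, y, lam, pen, beta, b0_init, tol, max_outer, max_inner, trace
    )
    return beta, b0, trace[:n_outer], n_outer, ok
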