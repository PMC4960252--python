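"""LASSO penalized logistic regression with bootstrap stability selection.

The model minimises  g(β) = −ℓ(y, β) + λ Σ|β_j|  over standardized
covariates, where ℓ is the binomial log-likelihood

    ℓ(y, β) = Σ_i y_i ln(π_i / (1 − π_i)) + Σ_i ln(1 − π_i),

π_i the fitted class-1 probability and λ the shrinkage tuning parameter.
λ is tuned along a glmnet-style log-spaced grid from λ_max (the smallest λ
zeroing every penalized coefficient, given by the KKT condition at β = 0)
down to 10⁻³·λ_max, picking either the full-data minimum-AIC fit (default)
or the minimum of the stratified 5-fold cross-validated deviance.

Because the L1 estimator is biased, no coefficient standard errors are
reported; instead the robustness of each selected metabolite is measured by
bootstrap *reproducibility*: the percentage of stratified with-replacement
resamples (default 1000) in which the refitted, re-tuned model assigns the
feature a non-zero coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import _cd
from .feature_table import FeatureTable

__all__ = [
    "LassoProblem",
    "LassoFit",
    "LassoPath",
    "StabilityResult",
    "make_problem",
    "lambda_max",
    "fit_lasso_logistic",
    "aic",
    "select_lambda",
    "bootstrap_stability",
    "select_by_stability",
]


# ----------------------------------------------------------------------
# Problem construction
# ----------------------------------------------------------------------
@dataclass
class LassoProblem:
    """Standardized design matrix and 0/1 response for the penalized fit."""

    X: np.ndarray                 # n × p, columns mean 0 / sd 1
    y: np.ndarray                 # 0/1
    feature_ids: list
    col_means: np.ndarray
    col_sds: np.ndarray
    class_codes: dict             # group label -> 0/1
    penalty_weights: np.ndarray = None  # 1 penalized, 0 never penalized

    def __post_init__(self) -> None:
        if self.penalty_weights is None:
            self.penalty_weights = np.ones(self.X.shape[1])
        if set(np.unique(self.y)) != {0.0, 1.0}:
            raise ValueError("y must contain both classes coded 0/1")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def make_problem(t: FeatureTable) -> LassoProblem:
    """Standardize the study-sample intensities and 0/1-code the groups.

    Group coding is lexicographic: first label → 0, second → 1.  Zero-
    variance columns cannot be standardized and raise, listing the ids.
    """
    X = t.study_intensities().to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("impute missing values before modelling")
    ga, gb = t.study_groups
    codes = {ga: 0.0, gb: 1.0}
    y = t.study_labels().map(codes).to_numpy(dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        ids = [t.feature_ids[j] for j in zero]
        raise ValueError(f"zero-variance features cannot be standardized: {ids}")
    Z = (X - means) / sds
    return LassoProblem(np.ascontiguousarray(Z), y, list(t.feature_ids), means, sds, codes)


def lambda_max(prob: LassoProblem) -> float:
    """Smallest λ at which every penalized coefficient is zero.

    With the intercept profiled out at β = 0 the fitted probabilities are
    ȳ, so the KKT condition gives λ_max = max_j |x_jᵀ(y − ȳ)| over the
    penalized features.
    """
    resid = prob.y - prob.y.mean()
    grad = np.abs(prob.X.T @ resid)
    pen = prob.penalty_weights > 0
    return float(grad[pen].max())


# ----------------------------------------------------------------------
# Single fit
# ----------------------------------------------------------------------
@dataclass
class LassoFit:
    lam: float
    intercept: float
    beta: np.ndarray              # standardized scale
    beta_raw: np.ndarray          # original-intensity scale
    log_likelihood: float
    aic: float
    active_set: np.ndarray        # indices with beta != 0
    converged: bool
    n_iter: int
    objective_trace: np.ndarray = field(default=None, repr=False)

    @property
    def deviance(self) -> float:
        return -2.0 * self.log_likelihood


def _log_likelihood(X, y, beta, b0) -> float:
    eta = X @ beta + b0
    # y*eta - log(1+exp(eta)), numerically stable
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _wrap_fit(prob, lam, beta, b0, trace, n_iter, conv) -> LassoFit:
    # snap numerically-zero coefficients (float fuzz exactly at the KKT
    # boundary, e.g. at lambda_max) to exact zeros
    beta = np.where(np.abs(beta) > 1e-12, beta, 0.0)
    ll = _log_likelihood(prob.X, prob.y, beta, b0)
    active = np.flatnonzero(beta != 0)
    return LassoFit(
        lam=float(lam),
        intercept=float(b0),
        beta=beta.copy(),
        beta_raw=beta / prob.col_sds,
        log_likelihood=ll,
        aic=-2.0 * ll + 2.0 * (active.size + 1),
        active_set=active,
        converged=bool(conv),
        n_iter=int(n_iter),
        objective_trace=trace,
    )


def fit_lasso_logistic(
    prob: LassoProblem,
    lam: float,
    init: np.ndarray | None = None,
    tol: float = 1e-7,
    max_iter: int = 10_000,
) -> LassoFit:
    """Coordinate-descent fit at one λ (IRLS outer loop, soft-thresholding).

    The intercept is unpenalized; convergence is max coefficient change
    below ``tol``.  Non-convergence returns the fit with ``converged=False``
    and a warning (at λ = 0 on separable data the coefficients are capped by
    the iteration limit).
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    beta0 = np.zeros(prob.p) if init is None else np.asarray(init, dtype=float)
    ybar = prob.y.mean()
    b0_init = float(np.log(ybar / (1 - ybar)))
    beta, b0, trace, n_outer, conv = _cd.fit_single(
        prob.X, prob.y, lam, prob.penalty_weights, beta0, b0_init,
        tol, max_iter, 1000,
    )
    if not conv:
        warnings.warn(f"coordinate descent did not converge at lambda={lam:g}")
    return _wrap_fit(prob, lam, beta, b0, trace, n_outer, conv)


def aic(fit: LassoFit) -> float:
    """AIC = −2ℓ + 2k with k = |active set| + 1 (intercept)."""
    return float(fit.aic)


def kkt_violation(prob: LassoProblem, fit: LassoFit) -> float:
    """Worst KKT residual: max(|grad|−λ)₊ inactive, max||grad|−λ| active."""
    eta = prob.X @ fit.beta + fit.intercept
    pi = 1.0 / (1.0 + np.exp(-eta))
    grad = prob.X.T @ (prob.y - pi)
    lam = fit.lam * prob.penalty_weights
    active = fit.beta != 0
    worst = 0.0
    if (~active).any():
        worst = max(worst, float(np.max(np.abs(grad[~active]) - lam[~active])))
    if active.any():
        worst = max(worst, float(np.max(np.abs(np.abs(grad[active]) - lam[active]))))
    return worst


# ----------------------------------------------------------------------
# Path and λ selection
# ----------------------------------------------------------------------
@dataclass
class LassoPath:
    lambda_grid: np.ndarray
    fits: list
    lambda_selected: float
    selection_rule: str

    @property
    def selected_fit(self) -> LassoFit:
        idx = int(np.flatnonzero(self.lambda_grid == self.lambda_selected)[0])
        return self.fits[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lambda": self.lambda_grid,
                "df": [f.active_set.size for f in self.fits],
                "log_likelihood": [f.log_likelihood for f in self.fits],
                "aic": [f.aic for f in self.fits],
                "deviance": [f.deviance for f in self.fits],
            }
        )


def default_grid(prob: LassoProblem, n_points: int = 100, ratio: float = 1e-3) -> np.ndarray:
    """Log-spaced decreasing λ grid from λ_max down to ratio·λ_max."""
    lmax = lambda_max(prob)
    return np.geomspace(lmax, ratio * lmax, n_points)


def _fit_path(prob: LassoProblem, grid: np.ndarray, tol: float, max_iter: int):
    betas, b0s, iters, conv = _cd.fit_path(
        prob.X, prob.y, np.ascontiguousarray(grid, dtype=float),
        prob.penalty_weights, tol, max_iter, 1000,
    )
    return [
        _wrap_fit(prob, grid[l], betas[l], b0s[l], None, iters[l], conv[l])
        for l in range(grid.size)
    ]


def select_lambda(
    prob: LassoProblem,
    grid: np.ndarray | None = None,
    rule: str = "aic",
    k: int = 5,
    seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 500,
) -> LassoPath:
    """Tune λ along a decreasing grid with warm starts.

    ``rule='aic'``: fit on the full data at every λ and take the minimum
    AIC (ties resolved toward larger λ, the sparser model).
    ``rule='cv_deviance'``: stratified k-fold with per-fold standardization,
    minimising the mean held-out deviance.  The returned path always carries
    the full-data fits.
    """
    if grid is None:
        grid = default_grid(prob)
    grid = np.asarray(grid, dtype=float)
    if grid.size > 1 and np.any(np.diff(grid) >= 0):
        raise ValueError("lambda grid must be strictly decreasing")
    fits = _fit_path(prob, grid, tol, max_iter)

    if rule == "aic":
        scores = np.array([f.aic for f in fits])
    elif rule == "cv_deviance":
        scores = _cv_deviance(prob, grid, k, seed, tol, max_iter)
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    # np.argmin returns the first minimum; the grid is decreasing, so ties
    # resolve toward larger lambda (sparser model)
    best = int(np.argmin(scores))
    return LassoPath(grid, fits, float(grid[best]), rule)


def _cv_deviance(prob, grid, k, seed, tol, max_iter) -> np.ndarray:
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    dev = np.zeros((k, grid.size))
    for f, (train, test) in enumerate(skf.split(prob.X, prob.y)):
        if len(np.unique(prob.y[train])) < 2:  # pragma: no cover - stratified
            raise ValueError("fold lacks both classes")
        Xtr = prob.X[train]
        means, sds = Xtr.mean(axis=0), Xtr.std(axis=0, ddof=1)
        keep = sds > 0
        Ztr = np.ascontiguousarray((Xtr[:, keep] - means[keep]) / sds[keep])
        Zte = (prob.X[test][:, keep] - means[keep]) / sds[keep]
        sub = LassoProblem(
            Ztr, prob.y[train], [prob.feature_ids[j] for j in np.flatnonzero(keep)],
            means[keep], sds[keep], prob.class_codes,
            penalty_weights=prob.penalty_weights[keep],
        )
        for l, fit_l in enumerate(_fit_path(sub, grid, tol, max_iter)):
            dev[f, l] = -2.0 * _log_likelihood(
                Zte, prob.y[test], fit_l.beta, fit_l.intercept
            )
    return dev.mean(axis=0)


# ----------------------------------------------------------------------
# Bootstrap stability
# ----------------------------------------------------------------------
@dataclass
class StabilityResult:
    n_boot: int
    feature_ids: list
    inclusion_count: np.ndarray
    seed: int
    active_sets: list = field(default=None, repr=False)

    @property
    def reproducibility(self) -> np.ndarray:
        """Per-feature inclusion percentage over the bootstrap resamples."""
        return 100.0 * self.inclusion_count / self.n_boot

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "inclusion_count": self.inclusion_count,
                "reproducibility_pct": self.reproducibility,
            }
        ).to_csv(path, sep="\t", index=False)


def bootstrap_stability(
    t: FeatureTable,
    n_boot: int = 1000,
    seed: int = 0,
    rule: str = "aic",
    grid_size: int = 100,
    grid_ratio: float = 1e-3,
    k: int = 5,
    keep_sets: bool = False,
) -> StabilityResult:
    """Bootstrap reproducibility of the LASSO selection.

    Each resample draws samples with replacement stratified by group
    (preserving the design), re-standardizes, re-tunes λ and refits; a
    feature's reproducibility is the percentage of resamples in which it
    enters the selected model.  Features constant within a resample are
    excluded from that resample's model and counted as not selected.
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    study = t.study_intensities().to_numpy(dtype=float)
    if np.isnan(study).any():
        raise ValueError("impute missing values before modelling")
    ga, gb = t.study_groups
    labels = t.study_labels().to_numpy()
    idx_a = np.flatnonzero(labels == ga)
    idx_b = np.flatnonzero(labels == gb)
    y_full = (labels == gb).astype(float)
    fids = list(t.feature_ids)
    counts = np.zeros(len(fids), dtype=int)
    sets = [] if keep_sets else None

    for _ in range(n_boot):
        take = np.concatenate(
            [rng.choice(idx_a, size=idx_a.size, replace=True),
             rng.choice(idx_b, size=idx_b.size, replace=True)]
        )
        Xb = study[take]
        yb = y_full[take]
        means, sds = Xb.mean(axis=0), Xb.std(axis=0, ddof=1)
        keep = sds > 0
        Zb = np.ascontiguousarray((Xb[:, keep] - means[keep]) / sds[keep])
        sub = LassoProblem(
            Zb, yb, [fids[j] for j in np.flatnonzero(keep)],
            means[keep], sds[keep], {ga: 0.0, gb: 1.0},
        )
        fold_seed = int(rng.integers(0, 2**31 - 1))
        path = select_lambda(
            sub, default_grid(sub, grid_size, grid_ratio), rule, k, fold_seed
        )
        active = path.selected_fit.active_set
        chosen = np.flatnonzero(keep)[active]
        counts[chosen] += 1
        if keep_sets:
            sets.append({fids[j] for j in chosen})

    return StabilityResult(n_boot, fids, counts, seed, sets)


def select_by_stability(
    s: StabilityResult,
    base_path: LassoPath,
    min_reproducibility: float = 90.0,
) -> pd.DataFrame:
    """Report the full-data active set annotated with reproducibility.

    Members below ``min_reproducibility`` are flagged, not removed — the
    selection is the full-data model; the bootstrap only qualifies it.
    """
    fit = base_path.selected_fit
    if fit.beta.size != len(s.feature_ids):
        raise ValueError("stability result and path cover different feature sets")
    repro = s.reproducibility
    out = pd.DataFrame(
        {
            "feature_id": [s.feature_ids[j] for j in fit.active_set],
            "beta": fit.beta[fit.active_set],
            "reproducibility_pct": [repro[j] for j in fit.active_set],
        }
    )
    out["flagged"] = out["reproducibility_pct"] < min_reproducibility
    return out
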