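"""PCA screening and OPLS-DA with VIP-based variable selection.

PCA (with a Hotelling's T² limit from the F distribution) is the unsupervised
screen: QC samples should cluster tightly and strongly atypical samples are
flagged as outliers.  OPLS-DA is the supervised model: an orthogonal-signal-
correction (OSC) step strips class-uncorrelated variation from X before a
single predictive PLS component is fitted against the ±1 class code, so the
predictive weight vector carries all the between-class information.  Variable
influence is summarised by VIP (variable importance in projection), whose
squares average to one; VIP > 1 is the conventional selection cut-off.  Model
quality is R²Y (goodness of fit) and Q² (predictive ability, from stratified
7-fold cross-validation, 1 − PRESS/SS).

The OPLS recursion, for centered/scaled X (n×p) and centered class code y:

    w ∝ Xᵀy / ‖Xᵀy‖                        (predictive weights)
    repeat for each orthogonal component:
        t = Xw;  p_load = Xᵀt / tᵀt
        w_orth ∝ p_load − (wᵀp_load) w     (Y-orthogonal direction)
        t_orth = X w_orth;  p_orth = Xᵀt_orth / t_orthᵀt_orth
        X ← X − t_orth p_orthᵀ              (OSC deflation)
    t = Xw;  c = yᵀt / tᵀt                 (predictive component)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .feature_table import FeatureTable
from .preprocess import ScalingSpec, apply_scaler, fit_scaler

__all__ = [
    "PcaModel",
    "OplsModel",
    "fit_pca",
    "hotelling_outliers",
    "fit_opls_da",
    "opls_da_on_table",
    "vip",
    "q2_cv",
    "select_by_vip",
]


def _sign_fix(v: np.ndarray) -> float:
    """Deterministic sign convention: largest-|.| element made positive."""
    idx = int(np.argmax(np.abs(v)))
    return 1.0 if v[idx] >= 0 else -1.0


# ----------------------------------------------------------------------
# PCA + Hotelling's T2
# ----------------------------------------------------------------------
@dataclass
class PcaModel:
    n_components: int
    scores: np.ndarray          # n × A
    loadings: np.ndarray        # p × A, orthonormal columns
    explained_variance: np.ndarray  # proportion per component
    eigenvalues: np.ndarray     # score variances (n−1 denominator)
    n_samples: int


def fit_pca(X: np.ndarray, n_components: int) -> PcaModel:
    """PCA of an already centered/scaled matrix via SVD.

    Deterministic sign convention: each loading's largest-magnitude element
    is positive.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(n-1, p)={min(n - 1, p)}"
        )
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    V = Vt[:n_components].T  # p × A
    signs = np.array([_sign_fix(V[:, a]) for a in range(n_components)])
    V = V * signs
    scores = X @ V
    eig = s**2 / (n - 1)
    total = np.sum(X**2) / (n - 1)
    explained = eig[:n_components] / total
    return PcaModel(n_components, scores, V, explained, eig[:n_components], n)


def hotelling_outliers(m: PcaModel, confidence: float = 0.95) -> np.ndarray:
    """Flag samples whose Hotelling's T² exceeds the F-distribution limit.

    T²_i = Σ_a t_ia²/λ_a with λ_a the score variance; the limit is
    A(n−1)(n+1) / (n(n−A)) · F⁻¹(confidence; A, n−A).
    """
    A, n = m.n_components, m.n_samples
    if A < 2:
        raise ValueError("Hotelling screening needs at least 2 components")
    if n <= A:
        raise ValueError("need more samples than components")
    t2 = np.sum(m.scores**2 / m.eigenvalues, axis=1)
    limit = A * (n - 1) * (n + 1) / (n * (n - A)) * stats.f.ppf(confidence, A, n - A)
    return t2 > limit


# ----------------------------------------------------------------------
# OPLS-DA
# ----------------------------------------------------------------------
@dataclass
class OplsModel:
    """Fitted OPLS-DA state: one predictive + ``n_orth`` orthogonal components."""

    w: np.ndarray               # predictive weights, unit norm
    t: np.ndarray               # predictive scores
    p_load: np.ndarray          # predictive loadings
    c: float                    # y-loading
    w_orth: np.ndarray          # K × p
    t_orth: np.ndarray          # K × n
    p_orth: np.ndarray          # K × p
    n_orth: int
    r2y: float
    class_codes: dict
    y_mean: float
    scaling: ScalingSpec | None = None
    feature_ids: list = field(default_factory=list)
    q2: float | None = None
    vip_: np.ndarray | None = None

    @property
    def vip(self) -> np.ndarray:
        if self.vip_ is None:
            self.vip_ = vip(self)
        return self.vip_


def fit_opls_da(X: np.ndarray, y: np.ndarray, n_orth: int = 1) -> OplsModel:
    """Fit OPLS-DA on a centered/scaled matrix and ±1 class codes.

    ``y`` is centered internally so unbalanced designs keep a zero-mean
    response.  Raises when y is orthogonal to every column (no predictive
    variation).
    """
    X = np.asarray(X, dtype=float).copy()
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {-1.0, 1.0}:
        raise ValueError("y must contain class codes +1/-1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    y_mean = float(y.mean())
    yc = y - y_mean

    w = X.T @ yc
    norm = np.linalg.norm(w)
    if norm < 1e-12:
        raise ValueError("no predictive variation: y orthogonal to every column")
    w = w / norm * _sign_fix(w / norm)

    p_dim = X.shape[1]
    W_o, T_o, P_o = [], [], []
    for _ in range(n_orth):
        t = X @ w
        p_load = X.T @ t / (t @ t)
        w_o = p_load - (w @ p_load) * w
        nrm = np.linalg.norm(w_o)
        if nrm < 1e-12:
            break  # no orthogonal variation left
        w_o = w_o / nrm * _sign_fix(w_o / nrm)
        t_o = X @ w_o
        p_o = X.T @ t_o / (t_o @ t_o)
        X = X - np.outer(t_o, p_o)
        W_o.append(w_o)
        T_o.append(t_o)
        P_o.append(p_o)

    t = X @ w
    c = float(yc @ t / (t @ t))
    p_load = X.T @ t / (t @ t)
    resid = yc - t * c
    ss = float(yc @ yc)
    r2y = 1.0 - float(resid @ resid) / ss if ss > 0 else 0.0

    K = len(W_o)
    shape = (K, p_dim) if K else (0, p_dim)
    return OplsModel(
        w=w,
        t=t,
        p_load=p_load,
        c=c,
        w_orth=np.array(W_o).reshape(shape),
        t_orth=np.array(T_o).reshape((K, X.shape[0]) if K else (0, X.shape[0])),
        p_orth=np.array(P_o).reshape(shape),
        n_orth=K,
        r2y=r2y,
        class_codes={},
        y_mean=y_mean,
    )


def _class_codes(groups: list[str]) -> dict:
    """+1/−1 codes in lexicographic label order (first label → +1)."""
    return {groups[0]: 1.0, groups[1]: -1.0}


def opls_da_on_table(
    t: FeatureTable,
    scaling: str = "uv",
    n_orth: int = 1,
) -> OplsModel:
    """Scale the study samples of an imputed table and fit OPLS-DA.

    Scaler statistics are fitted on the study samples only (QCs excluded).
    """
    X = t.study_intensities().to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("impute missing values before modelling")
    codes = _class_codes(t.study_groups)
    y = t.study_labels().map(codes).to_numpy(dtype=float)
    spec = fit_scaler(X, scaling)
    model = fit_opls_da(apply_scaler(X, spec), y, n_orth)
    model.scaling = spec
    model.class_codes = codes
    model.feature_ids = t.feature_ids
    return model


def opls_predict(m: OplsModel, X_new: np.ndarray) -> np.ndarray:
    """Predict centered class codes: OSC-deflate new data, then ŷ = t·c."""
    X = np.asarray(X_new, dtype=float).copy()
    for k in range(m.n_orth):
        t_o = X @ m.w_orth[k]
        X = X - np.outer(t_o, m.p_orth[k])
    return (X @ m.w) * m.c


# ----------------------------------------------------------------------
# VIP
# ----------------------------------------------------------------------
def vip(m: OplsModel) -> np.ndarray:
    """Variable importance in projection over the predictive component(s).

    VIP_j = sqrt( p · Σ_a SSY_a (w_aj/‖w_a‖)² / Σ_a SSY_a ); with the single
    predictive component this reduces to sqrt(p)·|w_j| for unit-norm w, so
    mean(VIP²) = 1.
    """
    # sqrt(p)·|w_j|/‖w‖ computed as |w_j|/sqrt(mean(w²)) so the symmetric
    # case gives exactly 1
    return np.abs(m.w) / np.sqrt(np.mean(m.w**2))


def select_by_vip(m: OplsModel, threshold: float = 1.0) -> set[str]:
    """Feature ids with VIP strictly above the threshold."""
    if not m.feature_ids:
        raise ValueError("model carries no feature ids; fit via opls_da_on_table")
    v = m.vip
    return {fid for fid, vj in zip(m.feature_ids, v) if vj > threshold}


# ----------------------------------------------------------------------
# Cross-validated Q2
# ----------------------------------------------------------------------
def q2_cv(
    t: FeatureTable,
    scaling: str = "uv",
    n_orth: int = 1,
    k: int = 7,
    seed: int = 0,
    refit_scaler: bool = True,
) -> float:
    """Stratified k-fold Q² = 1 − PRESS/SS for the OPLS-DA class prediction.

    The scaler is refitted inside each training fold by default (leakage-safe);
    ``refit_scaler=False`` mimics software that scales the whole matrix once.
    """
    X_all = t.study_intensities().to_numpy(dtype=float)
    codes = _class_codes(t.study_groups)
    y_all = t.study_labels().map(codes).to_numpy(dtype=float)
    counts = np.unique(y_all, return_counts=True)[1]
    if k > counts.min():
        raise ValueError(f"k={k} exceeds the smaller class count {counts.min()}")

    if not refit_scaler:
        global_spec = fit_scaler(X_all, scaling)

    press = 0.0
    ss = 0.0
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for train, test in skf.split(X_all, y_all):
        if len(np.unique(y_all[train])) < 2:  # pragma: no cover - stratified
            raise ValueError("fold lacks both classes")
        spec = fit_scaler(X_all[train], scaling) if refit_scaler else global_spec
        model = fit_opls_da(apply_scaler(X_all[train], spec), y_all[train], n_orth)
        y_train_mean = y_all[train].mean()
        yhat = opls_predict(model, apply_scaler(X_all[test], spec)) + y_train_mean
        press += float(np.sum((y_all[test] - yhat) ** 2))
        ss += float(np.sum((y_all[test] - y_train_mean) ** 2))
    return 1.0 - press / ss
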