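"""Centering and dispersion-based scaling (autoscaling vs Pareto).

Both scalings divide each mean-centered feature by a per-feature factor:
unit-variance (UV, autoscaling) uses the standard deviation, so every
feature ends up with sd 1 and the analysis runs on correlations; Pareto
uses the square root of the standard deviation, compressing high-variance
features less, so large fold changes stay more dominant than under UV.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

__all__ = ["ScalingSpec", "fit_scaler", "apply_scaler", "invert_scaler", "log_transform"]

_METHODS = ("none", "uv", "pareto")


@dataclass
class ScalingSpec:
    """Fitted per-feature centering means and scaling factors."""

    method: str
    center: bool
    means: np.ndarray
    factors: np.ndarray

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        self.means = np.asarray(self.means, dtype=float)
        self.factors = np.asarray(self.factors, dtype=float)
        if self.means.shape != self.factors.shape:
            raise ValueError("means and factors must have equal length")
        if self.method != "none" and np.any(self.factors <= 0):
            raise ValueError("scaling factors must be strictly positive")

    @property
    def n_features(self) -> int:
        return self.means.size

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["means"] = self.means.tolist()
        d["factors"] = self.factors.tolist()
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "ScalingSpec":
        d = json.loads(s)
        return cls(d["method"], d["center"], np.array(d["means"]), np.array(d["factors"]))


def fit_scaler(X: np.ndarray, method: str = "uv", center: bool = True) -> ScalingSpec:
    """Fit centering means and scaling factors on a complete matrix.

    Standard deviations use the n-1 denominator.  Zero-variance features
    cannot be scaled and raise, listing the offending column indices.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    if np.isnan(X).any():
        raise ValueError("missing values must be imputed before scaling")
    means = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if method == "none":
        factors = np.ones_like(sd)
    else:
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            raise ValueError(f"zero-variance features cannot be scaled: columns {zero.tolist()}")
        factors = sd if method == "uv" else np.sqrt(sd)
        if method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
    return ScalingSpec(method, center, means, factors)


def apply_scaler(X: np.ndarray, spec: ScalingSpec) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[1] != spec.n_features:
        raise ValueError(
            f"matrix has {X.shape[1]} features, scaler was fitted on {spec.n_features}"
        )
    out = X - spec.means if spec.center else X.copy()
    return out / spec.factors


def invert_scaler(Z: np.ndarray, spec: ScalingSpec) -> np.ndarray:
    Z = np.asarray(Z, dtype=float)
    if Z.shape[1] != spec.n_features:
        raise ValueError("dimension mismatch")
    out = Z * spec.factors
    return out + spec.means if spec.center else out


def log_transform(t, base: float = np.e, offset: float = 0.0):
    """Elementwise log of a :class:`FeatureTable`; missingness is preserved."""
    from .feature_table import FeatureTable

    X = t.intensities
    shifted = X + offset
    if (shifted[X.notna()] <= 0).any().any():
        raise ValueError("log_transform requires intensity + offset > 0")
    out = np.log(shifted) / np.log(base)
    return FeatureTable(out, t.feature_meta.copy(), t.sample_meta.copy(), log_scale=True)
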