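"""Per-feature two-group testing with normality-driven test choice and BH-FDR.

For each feature the test is chosen by a gate: Shapiro-Wilk normality in both
groups (alpha 0.05), then Brown-Forsythe (median-centered Levene) equality of
variances — Student's t when both gates pass, Welch's t when only normality
passes, Mann-Whitney U otherwise.  Two-sided p-values across all features are
then adjusted with the Benjamini-Hochberg step-up procedure; features with
adjusted q below the threshold form the FDR pre-selection handed to the
downstream OPLS-DA stage.

The branching logic and the BH step-up are implemented here; the classical
tests themselves come from :mod:`scipy.stats`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .feature_table import FeatureTable

__all__ = [
    "UnivariateResult",
    "choose_test",
    "run_univariate",
    "bh_adjust",
    "fdr_select",
]

STUDENT_T = "student_t"
WELCH_T = "welch_t"
MANN_WHITNEY = "mann_whitney"


@dataclass
class UnivariateResult:
    """Per-feature test records as a DataFrame indexed by feature_id.

    Columns: ``normal_a``, ``normal_b``, ``equal_var`` (nullable), ``test_used``,
    ``p_value``, ``q_value``, ``significant``.
    """

    records: pd.DataFrame
    alpha: float

    def to_tsv(self, path) -> None:
        out = self.records.copy()
        out.insert(0, "feature_id", out.index)
        out.to_csv(path, sep="\t", index=False)


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[~np.isnan(x)]


def choose_test(x_a, x_b, alpha: float = 0.05):
    """Pick the two-group test for one feature.

    Returns ``(test_used, normal_a, normal_b, equal_var)`` where ``equal_var``
    is ``None`` when the normality gate already failed.  Groups too small for
    Shapiro-Wilk (n < 3) fall back to Mann-Whitney with a warning.
    """
    a, b = _clean(x_a), _clean(x_b)
    if len(a) < 3 or len(b) < 3:
        warnings.warn("group too small for Shapiro-Wilk; falling back to Mann-Whitney")
        return MANN_WHITNEY, None, None, None
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        # Shapiro-Wilk is undefined for constant input; treat as non-normal
        return MANN_WHITNEY, False, False, None
    normal_a = stats.shapiro(a).pvalue > alpha
    normal_b = stats.shapiro(b).pvalue > alpha
    if not (normal_a and normal_b):
        return MANN_WHITNEY, normal_a, normal_b, None
    equal_var = stats.levene(a, b, center="median").pvalue > alpha
    return (STUDENT_T if equal_var else WELCH_T), normal_a, normal_b, equal_var


def _mann_whitney_p(a: np.ndarray, b: np.ndarray) -> float:
    # exact distribution for small tie-free samples, else normal approximation
    # with tie correction
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= 20 and not has_ties) else "asymptotic"
    return stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue


def run_univariate(t: FeatureTable, alpha: float = 0.05) -> UnivariateResult:
    """Test every feature between the two study groups and BH-adjust.

    Runs on raw (unscaled) intensities: per-feature linear scaling leaves the
    t, Welch and Mann-Whitney statistics invariant, so the order relative to
    scaling is immaterial.  Constant features yield p = 1 with a warning.
    """
    ga, gb = t.study_groups
    labels = t.study_labels()
    study = t.study_intensities()
    Xa = study.loc[(labels == ga).to_numpy()]
    Xb = study.loc[(labels == gb).to_numpy()]

    rows = []
    for fid in t.feature_ids:
        a, b = _clean(Xa[fid]), _clean(Xb[fid])
        if len(a) == 0 or len(b) == 0:
            warnings.warn(f"feature {fid} unobserved in a group; p set to 1")
            rows.append((fid, None, None, None, "none", 1.0))
            continue
        pooled = np.concatenate([a, b])
        if np.ptp(pooled) == 0:
            warnings.warn(f"feature {fid} constant in both groups; p set to 1")
            rows.append((fid, None, None, None, "none", 1.0))
            continue
        test, na, nb, ev = choose_test(a, b, alpha)
        if test == STUDENT_T:
            p = stats.ttest_ind(a, b, equal_var=True).pvalue
        elif test == WELCH_T:
            p = stats.ttest_ind(a, b, equal_var=False).pvalue
        else:
            p = _mann_whitney_p(a, b)
        rows.append((fid, na, nb, ev, test, float(p)))

    rec = pd.DataFrame(
        rows,
        columns=["feature_id", "normal_a", "normal_b", "equal_var", "test_used", "p_value"],
    ).set_index("feature_id")
    rec["q_value"] = bh_adjust(rec["p_value"].to_numpy())
    rec["significant"] = rec["q_value"] < alpha
    return UnivariateResult(rec, alpha)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Sort ascending, set q_(i) = min_{j >= i} p_(j) * m / j capped at 1, and
    return in the original order.  Thresholding q < a reproduces the classical
    step-up rejection set at level a.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def fdr_select(r: UnivariateResult, q_threshold: float = 0.05) -> set[str]:
    """Feature ids significant after FDR correction (strict q < threshold)."""
    rec = r.records
    return set(rec.index[rec["q_value"] < q_threshold])
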