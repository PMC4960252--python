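"""Synthetic untargeted LC-MS feature tables with known ground truth.

The generator emulates the structure of a two-group plasma metabolomics
study with pooled-QC injections:

* per-feature baseline log2 intensities spread over several orders of
  magnitude (log-normal raw intensities);
* a planted subset of discriminating features shifted between the groups by
  ``log2_fold_change`` (random direction per feature);
* block-structured biological variation — features within a block share a
  latent factor, giving within-block correlation ``within_block_corr`` and
  an overall biological CV of ``biological_cv`` (the multicollinearity that
  distinguishes LASSO behaviour from OPLS);
* multiplicative analytical noise at ``qc_cv`` on every injection;
* QC samples simulated as a pooled mean of the study samples' expected
  intensities plus analytical noise only;
* left-censoring: values below the feature's ``lod_quantile`` detection
  threshold are set missing (the MNAR mechanism the presence filters
  assume).

Coefficients of variation are converted to log-scale standard deviations via
the log-normal identity sigma = sqrt(ln(1 + CV^2)).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .feature_table import FeatureTable

__all__ = ["SimulationDesign", "GroundTruth", "simulate_study", "truth_metrics"]

LN2 = np.log(2.0)


@dataclass
class SimulationDesign:
    """Study-design parameters for the synthetic generator."""

    n_per_group: tuple = (50, 50)
    n_qc: int = 8
    p: int = 500
    n_true: int = 10
    log2_fold_change: float = 1.0
    qc_cv: float = 0.15
    biological_cv: float = 0.30
    block_size: int = 10
    within_block_corr: float = 0.6
    lod_quantile: float = 0.05
    seed: int = 0
    #: optionally draw the discriminating features from the lowest-baseline
    #: quantile (to study scaling sensitivity); None = uniformly at random
    true_baseline_quantile: float | None = None
    group_names: tuple = ("case", "control")

    def validate(self) -> None:
        if min(self.n_per_group) < 1 or self.n_qc < 0 or self.p < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.n_true <= self.p:
            raise ValueError("n_true must lie in [0, p]")
        if not 0 <= self.within_block_corr < 1:
            raise ValueError("within_block_corr must lie in [0, 1)")
        if self.qc_cv < 0 or self.biological_cv < 0:
            raise ValueError("CVs must be non-negative")
        if not 0 <= self.lod_quantile < 1:
            raise ValueError("lod_quantile must lie in [0, 1)")
        if self.block_size < 1:
            raise ValueError("block_size must be positive")


@dataclass
class GroundTruth:
    """Planted discriminating features with per-feature effect sign/size."""

    true_feature_ids: set
    effects_log2: dict  # feature_id -> signed log2 fold change

    def to_json(self) -> str:
        return json.dumps(
            {
                "true_feature_ids": sorted(self.true_feature_ids),
                "effects_log2": {k: self.effects_log2[k] for k in sorted(self.effects_log2)},
            },
            sort_keys=True,
        )


def _cv_to_log2_sd(cv: float) -> float:
    return np.sqrt(np.log1p(cv**2)) / LN2


def simulate_study(d: SimulationDesign) -> tuple[FeatureTable, GroundTruth]:
    """Generate a feature table plus its ground truth; bit-reproducible by seed."""
    d.validate()
    rng = np.random.default_rng(d.seed)
    n_a, n_b = d.n_per_group
    n_study = n_a + n_b
    p = d.p

    fids = [f"F{j:05d}" for j in range(p)]
    baseline = rng.normal(18.0, 2.0, size=p)  # log2 intensities ~ 3e4..7e6

    if d.n_true == 0:
        true_idx = np.array([], dtype=int)
    elif d.true_baseline_quantile is not None:
        cut = np.quantile(baseline, d.true_baseline_quantile)
        low = np.flatnonzero(baseline <= cut)
        true_idx = rng.choice(low, size=min(d.n_true, low.size), replace=False)
    else:
        true_idx = rng.choice(p, size=d.n_true, replace=False)
    signs = rng.choice([-1.0, 1.0], size=true_idx.size)

    effect = np.zeros(p)
    effect[true_idx] = signs * d.log2_fold_change

    group = np.array([0] * n_a + [1] * n_b)
    # expected log2 intensity per study sample (before biological/analytical noise)
    expected = baseline[None, :] + np.outer(group, effect)

    # block factor model for biological variation
    sd_bio = _cv_to_log2_sd(d.biological_cv)
    n_blocks = int(np.ceil(p / d.block_size))
    block_of = np.repeat(np.arange(n_blocks), d.block_size)[:p]
    factors = rng.normal(size=(n_study, n_blocks))
    idio = rng.normal(size=(n_study, p))
    rho = d.within_block_corr
    bio = sd_bio * (np.sqrt(rho) * factors[:, block_of] + np.sqrt(1 - rho) * idio)

    sd_an = _cv_to_log2_sd(d.qc_cv)
    study_log2 = expected + bio + sd_an * rng.normal(size=(n_study, p))

    # QC = pooled mean of the study samples' expected raw intensities,
    # re-injected with analytical noise only
    pooled = np.log2(np.mean(2.0**expected, axis=0))
    qc_log2 = pooled[None, :] + sd_an * rng.normal(size=(d.n_qc, p))

    X = np.vstack([2.0**study_log2, 2.0**qc_log2])

    # left-censoring at the per-feature detection limit
    if d.lod_quantile > 0:
        lod = np.quantile(2.0**study_log2, d.lod_quantile, axis=0)
        X = np.where(X < lod[None, :], np.nan, X)

    sample_ids = (
        [f"{d.group_names[0]}_{i:03d}" for i in range(n_a)]
        + [f"{d.group_names[1]}_{i:03d}" for i in range(n_b)]
        + [f"QC_{i:03d}" for i in range(d.n_qc)]
    )
    groups = (
        [d.group_names[0]] * n_a + [d.group_names[1]] * n_b + ["QC"] * d.n_qc
    )
    sm = pd.DataFrame(
        {"group": groups, "is_qc": [False] * n_study + [True] * d.n_qc},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    fm = pd.DataFrame(
        {
            "neutral_mass": np.round(rng.uniform(80.0, 1000.0, size=p), 4),
            "rt": np.round(rng.uniform(0.5, 20.0, size=p), 3),
        },
        index=pd.Index(fids, name="feature_id"),
    )
    intens = pd.DataFrame(X, index=sm.index, columns=fm.index)

    truth = GroundTruth(
        {fids[j] for j in true_idx},
        {fids[j]: float(effect[j]) for j in true_idx},
    )
    return FeatureTable(intens, fm, sm), truth


def truth_metrics(selected: set, truth: GroundTruth) -> dict:
    """Recall, precision, and false-discovery proportion of a selection."""
    sel = set(selected)
    true = set(truth.true_feature_ids)
    tp = len(sel & true)
    recall = tp / len(true) if true else float("nan")
    precision = tp / len(sel) if sel else float("nan")
    fdp = 1.0 - precision if sel else float("nan")
    return {"recall": recall, "precision": precision, "fdp": fdp}
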