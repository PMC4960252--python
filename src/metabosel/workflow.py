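"""Orchestration of the three variable-selection approaches and their comparison.

The pipeline, in fixed order: read (or simulate) → QA filtration → half-minimum
imputation → optional PCA/Hotelling outlier removal → the three approaches →
Venn comparison.

Approaches
----------
``opls_vip``      scale, fit OPLS-DA, keep VIP > 1 (no multiple-testing step).
``fdr_opls_vip``  univariate tests with BH-FDR pre-selection, then OPLS-DA and
                  VIP > 1 on the surviving features.
``lasso``         standardize, tune λ (min AIC by default), bootstrap the whole
                  model development for per-feature reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .feature_table import FeatureTable, apply_qa_pipeline, impute_half_min
from .multivariate import (
    fit_pca,
    hotelling_outliers,
    opls_da_on_table,
    q2_cv,
    select_by_vip,
)
from .penalized import (
    bootstrap_stability,
    default_grid,
    make_problem,
    select_by_stability,
    select_lambda,
)
from .preprocess import apply_scaler, fit_scaler
from .univariate import fdr_select, run_univariate

__all__ = [
    "SelectionReport",
    "remove_pca_outliers",
    "run_approach_opls",
    "run_approach_fdr_opls",
    "run_approach_lasso",
    "compare_selections",
    "run_all",
    "DEFAULT_CONFIG",
]

DEFAULT_CONFIG = {
    "qa": {"min_qc_fraction": 0.5, "max_cv": 0.20, "min_group_fraction": 0.8},
    "outlier_removal": {"enabled": False, "confidence": 0.95, "n_components": 2},
    "opls": {"n_orth": 1, "q2_folds": 7},
    "fdr": {"alpha": 0.05},
    "lasso": {
        "rule": "aic",
        "grid_size": 100,
        "grid_ratio": 1e-3,
        "folds": 5,
        "n_boot": 1000,
        "min_reproducibility": 90.0,
    },
    "simulate": {},
}


# ----------------------------------------------------------------------
@dataclass
class ApproachResult:
    name: str
    scaling: str | None
    selected: set
    extras: dict = field(default_factory=dict)


@dataclass
class SelectionReport:
    """Selections of the three approaches plus their Venn overlap counts."""

    approaches: list
    venn: dict          # 7 region counts keyed by membership pattern
    consensus: set

    def to_json(self) -> str:
        payload = {
            "approaches": [
                {
                    "name": a.name,
                    "scaling": a.scaling,
                    "n_selected": len(a.selected),
                    "selected": sorted(a.selected),
                    **{
                        k: v
                        for k, v in a.extras.items()
                        if isinstance(v, (int, float, str, bool))
                    },
                }
                for a in self.approaches
            ],
            "venn": self.venn,
            "consensus": sorted(self.consensus),
        }
        return json.dumps(payload, sort_keys=True, indent=2)


# ----------------------------------------------------------------------
def remove_pca_outliers(
    t: FeatureTable,
    confidence: float = 0.95,
    n_components: int = 2,
    scaling: str = "uv",
) -> tuple[FeatureTable, list]:
    """Single-pass Hotelling's T² screen on the study samples.

    Fits PCA once on the scaled study samples and drops flagged samples once
    (no iteration); QC samples are never dropped.
    """
    study = t.study_intensities()
    X = study.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("impute missing values before outlier screening")
    spec = fit_scaler(X, scaling)
    model = fit_pca(apply_scaler(X, spec), n_components)
    flags = hotelling_outliers(model, confidence)
    dropped = [sid for sid, f in zip(study.index, flags) if f]
    keep = [sid for sid in t.intensities.index if sid not in set(dropped)]
    return t.subset_samples(keep), dropped


# ----------------------------------------------------------------------
def run_approach_opls(
    t: FeatureTable, scaling: str = "uv", n_orth: int = 1, q2_folds: int = 7,
    seed: int = 0,
) -> ApproachResult:
    """OPLS-DA on all QA-filtered features; select VIP > 1."""
    model = opls_da_on_table(t, scaling, n_orth)
    model.q2 = q2_cv(t, scaling, n_orth, k=q2_folds, seed=seed)
    selected = select_by_vip(model)
    return ApproachResult(
        "opls_vip",
        scaling,
        selected,
        {"r2y": model.r2y, "q2": model.q2, "model": model},
    )


def run_approach_fdr_opls(
    t: FeatureTable, scaling: str = "uv", q_threshold: float = 0.05,
    n_orth: int = 1, q2_folds: int = 7, seed: int = 0,
) -> ApproachResult:
    """BH-FDR pre-selection, then OPLS-DA with VIP > 1 on the survivors."""
    uni = run_univariate(t, q_threshold)
    pre = fdr_select(uni, q_threshold)
    extras: dict = {"n_fdr_significant": len(pre), "univariate": uni}
    if len(pre) == 0:
        warnings.warn("FDR pre-selection is empty; skipping OPLS-DA")
        return ApproachResult("fdr_opls_vip", scaling, set(), extras)
    if len(pre) == 1:
        warnings.warn("FDR pre-selection has a single feature; skipping OPLS-DA")
        return ApproachResult("fdr_opls_vip", scaling, set(pre), extras)
    sub = t.subset_features(sorted(pre))
    model = opls_da_on_table(sub, scaling, n_orth)
    model.q2 = q2_cv(sub, scaling, n_orth, k=min(q2_folds, _min_class(sub)), seed=seed)
    extras.update({"r2y": model.r2y, "q2": model.q2, "model": model})
    return ApproachResult("fdr_opls_vip", scaling, select_by_vip(model), extras)


def _min_class(t: FeatureTable) -> int:
    return int(t.study_labels().value_counts().min())


def run_approach_lasso(
    t: FeatureTable,
    rule: str = "aic",
    grid_size: int = 100,
    grid_ratio: float = 1e-3,
    folds: int = 5,
    n_boot: int = 1000,
    min_reproducibility: float = 90.0,
    seed: int = 0,
) -> ApproachResult:
    """LASSO logistic regression with λ tuning and bootstrap reproducibility."""
    prob = make_problem(t)
    path = select_lambda(
        prob, default_grid(prob, grid_size, grid_ratio), rule, folds, seed
    )
    stab = bootstrap_stability(
        t, n_boot=n_boot, seed=seed, rule=rule,
        grid_size=grid_size, grid_ratio=grid_ratio, k=folds,
    )
    report = select_by_stability(stab, path, min_reproducibility)
    selected = set(report["feature_id"])
    repro = dict(zip(report["feature_id"], report["reproducibility_pct"]))
    extras = {
        "lambda_selected": path.lambda_selected,
        "path": path,
        "stability": stab,
        "report": report,
        "reproducibility": repro,
        "reproducibility_min": float(report["reproducibility_pct"].min()) if len(report) else float("nan"),
        "reproducibility_max": float(report["reproducibility_pct"].max()) if len(report) else float("nan"),
    }
    return ApproachResult("lasso", None, selected, extras)


# ----------------------------------------------------------------------
def compare_selections(a: set, b: set, c: set) -> SelectionReport:
    """All 7 Venn regions for three selections plus their consensus."""
    a, b, c = set(a), set(b), set(c)
    union = a | b | c
    venn = {"100": 0, "010": 0, "001": 0, "110": 0, "101": 0, "011": 0, "111": 0}
    for f in union:
        key = f"{int(f in a)}{int(f in b)}{int(f in c)}"
        venn[key] += 1
    return SelectionReport([], venn, a & b & c)


# ----------------------------------------------------------------------
def _merge_config(cfg: dict | None) -> dict:
    merged = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    for section, values in (cfg or {}).items():
        merged.setdefault(section, {}).update(values or {})
    return merged


def run_all(
    t: FeatureTable,
    cfg: dict | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> SelectionReport:
    """Run QA filtration, imputation, and the three approaches on one table.

    The OPLS approaches are run under both scalings; UV is the headline
    selection used in the Venn comparison, with Pareto reported alongside.
    A config + seed fully determines every output file.
    """
    cfg = _merge_config(cfg)
    filtered, logs = apply_qa_pipeline(t, **cfg["qa"])
    imputed, _ = impute_half_min(filtered)

    dropped: list = []
    if cfg["outlier_removal"].get("enabled"):
        imputed, dropped = remove_pca_outliers(
            imputed,
            cfg["outlier_removal"].get("confidence", 0.95),
            cfg["outlier_removal"].get("n_components", 2),
        )

    opls_cfg = cfg["opls"]
    results = []
    for scaling in ("uv", "pareto"):
        results.append(
            run_approach_opls(
                imputed, scaling, opls_cfg["n_orth"], opls_cfg["q2_folds"], seed
            )
        )
        results.append(
            run_approach_fdr_opls(
                imputed, scaling, cfg["fdr"]["alpha"],
                opls_cfg["n_orth"], opls_cfg["q2_folds"], seed,
            )
        )
    lasso_res = run_approach_lasso(imputed, seed=seed, **{
        k: v for k, v in cfg["lasso"].items()
        if k in {"rule", "grid_size", "grid_ratio", "folds", "n_boot", "min_reproducibility"}
    })
    results.append(lasso_res)

    uv_opls = next(r for r in results if r.name == "opls_vip" and r.scaling == "uv")
    uv_fdr = next(r for r in results if r.name == "fdr_opls_vip" and r.scaling == "uv")
    report = compare_selections(uv_opls.selected, uv_fdr.selected, lasso_res.selected)
    report.approaches = results

    if out_dir is not None:
        _write_outputs(Path(out_dir), report, logs, dropped)
    return report


def _write_outputs(out_dir: Path, report: SelectionReport, logs, dropped) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for a in report.approaches:
        tag = a.name if a.scaling is None else f"{a.name}_{a.scaling}"
        df = pd.DataFrame({"feature_id": sorted(a.selected)})
        if "reproducibility" in a.extras:
            df["reproducibility_pct"] = [
                a.extras["reproducibility"][f] for f in df["feature_id"]
            ]
        df.to_csv(out_dir / f"selection_{tag}.tsv", sep="\t", index=False)
    (out_dir / "report.json").write_text(report.to_json() + "\n")
    with open(out_dir / "qa_filter_log.jsonl", "w") as fh:
        for log in logs:
            fh.write(log.to_json() + "\n")
    (out_dir / "outliers_removed.json").write_text(
        json.dumps({"dropped_samples": sorted(dropped)}, sort_keys=True) + "\n"
    )


def hash_outputs(out_dir: str | Path) -> dict:
    """SHA-256 of every TSV/JSON output — the determinism fingerprint."""
    out = {}
    for path in sorted(Path(out_dir).glob("*")):
        if path.suffix in {".tsv", ".json", ".jsonl"}:
            out[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    return out


# ----------------------------------------------------------------------
# Plotting (optional outputs; never part of the numeric pipeline)
# ----------------------------------------------------------------------
def plot_scores(model, labels, path) -> None:
    """OPLS-DA score plot: predictive vs first orthogonal score."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    t1 = model.t
    t2 = model.t_orth[0] if model.n_orth else np.zeros_like(t1)
    for g in sorted(set(labels)):
        m = np.asarray(labels) == g
        ax.scatter(t1[m], t2[m], label=str(g), alpha=0.8)
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    ax.set_xlabel("t (predictive)")
    ax.set_ylabel("t_orth 1")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
    plt.close(fig)


def plot_venn(venn: dict, labels: tuple, path) -> None:
    """Three-circle Venn diagram annotated with the 7 region counts."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    fig, ax = plt.subplots(figsize=(5, 5))
    centers = [(-0.35, 0.25), (0.35, 0.25), (0.0, -0.4)]
    colors = ["tab:blue", "tab:orange", "tab:green"]
    for (x, y), c, lab in zip(centers, colors, labels):
        ax.add_patch(Circle((x, y), 0.75, alpha=0.3, color=c))
        ax.annotate(lab, (x, y + 0.85), ha="center")
    pos = {
        "100": (-0.7, 0.45), "010": (0.7, 0.45), "001": (0.0, -0.85),
        "110": (0.0, 0.55), "101": (-0.45, -0.25), "011": (0.45, -0.25),
        "111": (0.0, 0.05),
    }
    for key, (x, y) in pos.items():
        ax.annotate(str(venn.get(key, 0)), (x, y), ha="center", fontsize=12)
    ax.set_xlim(-1.6, 1.6)
    ax.set_ylim(-1.6, 1.6)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
    plt.close(fig)
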