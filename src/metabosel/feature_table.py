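"""Feature tables for untargeted LC-MS metabolomics and their QA filtration.

A *feature* is a (neutral mass, retention time) pair with a per-sample
abundance — a putative metabolite before identification.  The
:class:`FeatureTable` holds the samples-by-features intensity matrix together
with feature metadata (id, monoisotopic neutral mass in Da, retention time in
minutes) and sample metadata (group label, pooled-QC flag).  Missing values
(below detection limit / not integrated) are ``NaN``.

The quality-assurance cascade applied to vendor-aligned tables is

1. ``qc_presence_filter`` — keep features detected in at least 50% of the
   pooled-QC injections,
2. ``qc_cv_filter``       — keep features whose coefficient of variation
   across QC injections is strictly below 20%,
3. ``group_presence_filter`` — keep features detected in at least 80% of the
   samples of at least one study group.

"Present" means non-missing and strictly positive; undetected features are
exported by vendor software as 0 or blank cells, both of which are parsed as
missing here.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "QaFilterLog",
    "read_feature_table",
    "write_feature_table",
    "qc_presence_filter",
    "qc_cv_filter",
    "group_presence_filter",
    "apply_qa_pipeline",
    "impute_half_min",
]

#: Columns required in the sample-metadata file.
SAMPLE_META_COLUMNS = ("sample_id", "group", "is_qc")
#: Feature-metadata columns carried alongside the intensity matrix.
FEATURE_META_COLUMNS = ("feature_id", "neutral_mass", "rt")


class FeatureTableError(ValueError):
    """Raised when a table violates its structural invariants."""


@dataclass
class FeatureTable:
    """Samples-by-features intensity matrix with feature and sample metadata.

    Parameters
    ----------
    intensities
        DataFrame of non-negative intensities, rows indexed by ``sample_id``,
        columns by ``feature_id``; ``NaN`` marks a missing (undetected) value.
    feature_meta
        DataFrame indexed by ``feature_id`` with columns ``neutral_mass``
        (Da) and ``rt`` (minutes); either may be ``NaN``.
    sample_meta
        DataFrame indexed by ``sample_id`` with columns ``group``
        (exactly two study levels among non-QC samples) and ``is_qc`` (bool).
    """

    intensities: pd.DataFrame
    feature_meta: pd.DataFrame
    sample_meta: pd.DataFrame
    #: log-domain tables may hold negative values; raw-scale tables may not
    log_scale: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        X, fm, sm = self.intensities, self.feature_meta, self.sample_meta
        if X.shape != (len(sm), len(fm)):
            raise FeatureTableError(
                f"intensity matrix shape {X.shape} does not match "
                f"{len(sm)} samples x {len(fm)} features"
            )
        if not X.index.equals(sm.index):
            raise FeatureTableError("intensity rows and sample_meta ids differ")
        if not X.columns.equals(fm.index):
            raise FeatureTableError("intensity columns and feature_meta ids differ")
        if X.index.has_duplicates:
            dups = X.index[X.index.duplicated()].unique().tolist()
            raise FeatureTableError(f"duplicated sample ids: {dups}")
        if X.columns.has_duplicates:
            dups = X.columns[X.columns.duplicated()].unique().tolist()
            raise FeatureTableError(f"duplicated feature ids: {dups}")
        vals = X.to_numpy(dtype=float)
        if not self.log_scale and vals.size and np.nanmin(vals, initial=0.0) < 0:
            raise FeatureTableError("negative intensities are not allowed")
        groups = self.study_groups
        if len(groups) != 2:
            raise FeatureTableError(
                f"expected exactly 2 study groups, found {len(groups)}: {groups}"
            )

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def is_qc(self) -> pd.Series:
        return self.sample_meta["is_qc"].astype(bool)

    @property
    def study_groups(self) -> list[str]:
        """The study group labels (QC samples excluded), sorted."""
        study = self.sample_meta.loc[~self.is_qc, "group"]
        return sorted(study.unique().tolist())

    def qc_intensities(self) -> pd.DataFrame:
        return self.intensities.loc[self.is_qc.to_numpy()]

    def study_intensities(self) -> pd.DataFrame:
        return self.intensities.loc[(~self.is_qc).to_numpy()]

    def study_labels(self) -> pd.Series:
        return self.sample_meta.loc[~self.is_qc, "group"]

    # ------------------------------------------------------------------
    def subset_features(self, feature_ids: Sequence[str]) -> "FeatureTable":
        ids = [f for f in self.feature_ids if f in set(feature_ids)]
        return FeatureTable(
            self.intensities[ids].copy(),
            self.feature_meta.loc[ids].copy(),
            self.sample_meta.copy(),
            log_scale=self.log_scale,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        keep = set(sample_ids)
        mask = self.intensities.index.isin(keep)
        return FeatureTable(
            self.intensities.loc[mask].copy(),
            self.feature_meta.copy(),
            self.sample_meta.loc[mask].copy(),
            log_scale=self.log_scale,
        )

    def presence_mask(self) -> pd.DataFrame:
        """Boolean mask: non-missing AND strictly positive."""
        X = self.intensities
        return X.notna() & (X > 0)


@dataclass
class QaFilterLog:
    """Record of one QA filtration stage (the cascade bookkeeping)."""

    stage_name: str
    n_features_before: int
    n_features_after: int
    removed_feature_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_features_after != self.n_features_before - len(
            self.removed_feature_ids
        ):
            raise ValueError("inconsistent QaFilterLog counts")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------
def read_feature_table(
    intensity_path,
    sample_meta_path,
    orientation: str = "samples_in_columns",
    sep: str = ",",
    zero_as_missing: bool = True,
    missing_sentinel: float = 0.0,
) -> FeatureTable:
    """Read a delimited intensity table plus sample metadata.

    ``samples_in_columns`` is the vendor-export layout: one row per feature
    with ``feature_id``, ``neutral_mass``, ``rt`` columns followed by one
    column per sample.  ``samples_in_rows`` is the modelling layout: one row
    per sample with a ``sample_id`` column followed by one column per feature
    (feature mass/RT are then unavailable and stored as NaN).

    Empty cells, "NA" and (when ``zero_as_missing``) the sentinel value are
    parsed as missing.
    """
    raw = pd.read_csv(
        intensity_path, sep=sep, na_values=["NA", ""], float_precision="round_trip"
    )
    if orientation == "samples_in_columns":
        missing_cols = [c for c in FEATURE_META_COLUMNS if c not in raw.columns]
        if missing_cols:
            raise FeatureTableError(
                f"intensity file lacks feature metadata columns {missing_cols}"
            )
        fm = raw[list(FEATURE_META_COLUMNS)].copy()
        fm["feature_id"] = fm["feature_id"].astype(str)
        fm = fm.set_index("feature_id")
        X = raw.drop(columns=list(FEATURE_META_COLUMNS))
        X.index = fm.index
        X = X.T  # rows now samples
        X.index = X.index.astype(str)
    elif orientation == "samples_in_rows":
        if "sample_id" not in raw.columns:
            raise FeatureTableError("samples_in_rows layout requires a sample_id column")
        X = raw.set_index(raw["sample_id"].astype(str)).drop(columns=["sample_id"])
        fm = pd.DataFrame(
            {"neutral_mass": np.nan, "rt": np.nan}, index=X.columns.astype(str)
        )
        fm.index.name = "feature_id"
    else:
        raise ValueError(f"unknown orientation {orientation!r}")

    X = X.astype(float)
    if zero_as_missing:
        X = X.mask(X == missing_sentinel)

    sm = pd.read_csv(sample_meta_path, sep=sep)
    missing_cols = [c for c in SAMPLE_META_COLUMNS if c not in sm.columns]
    if missing_cols:
        raise FeatureTableError(f"sample metadata lacks columns {missing_cols}")
    sm["sample_id"] = sm["sample_id"].astype(str)
    if sm["sample_id"].duplicated().any():
        dups = sm.loc[sm["sample_id"].duplicated(), "sample_id"].tolist()
        raise FeatureTableError(f"duplicated sample ids in metadata: {dups}")
    sm = sm.set_index("sample_id")
    sm["is_qc"] = sm["is_qc"].astype(bool)

    only_meta = sorted(set(sm.index) - set(X.index))
    only_matrix = sorted(set(X.index) - set(sm.index))
    if only_meta or only_matrix:
        raise FeatureTableError(
            "sample id mismatch between intensity matrix and metadata: "
            f"metadata-only={only_meta}, matrix-only={only_matrix}"
        )
    X = X.loc[sm.index]  # align order to metadata
    return FeatureTable(X, fm, sm)


def write_feature_table(
    t: FeatureTable,
    intensity_path,
    sample_meta_path,
    orientation: str = "samples_in_columns",
    sep: str = ",",
) -> None:
    """Write a table in a layout :func:`read_feature_table` round-trips.

    Finite intensities are written with ``repr`` precision so that a
    read-back reproduces them bit-exactly; missing cells are left empty.
    """
    if orientation == "samples_in_columns":
        meta = t.feature_meta.copy()
        meta.insert(0, "feature_id", meta.index)
        wide = t.intensities.T
        wide.index = meta.index
        out = pd.concat([meta, wide], axis=1)
        out.to_csv(intensity_path, sep=sep, index=False)
    elif orientation == "samples_in_rows":
        out = t.intensities.copy()
        out.insert(0, "sample_id", out.index)
        out.to_csv(intensity_path, sep=sep, index=False)
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    sm = t.sample_meta.copy()
    sm.insert(0, "sample_id", sm.index)
    sm.to_csv(sample_meta_path, sep=sep, index=False)


# ----------------------------------------------------------------------
# QA filters
# ----------------------------------------------------------------------
def _filtered(t: FeatureTable, keep: pd.Series, stage: str) -> tuple[FeatureTable, QaFilterLog]:
    removed = [f for f, k in keep.items() if not k]
    kept_ids = [f for f in t.feature_ids if keep[f]]
    log = QaFilterLog(stage, t.n_features, len(kept_ids), removed)
    return t.subset_features(kept_ids), log


def qc_presence_filter(
    t: FeatureTable, min_qc_fraction: float = 0.5
) -> tuple[FeatureTable, QaFilterLog]:
    """Keep features present in at least ``min_qc_fraction`` of QC injections."""
    if not 0 < min_qc_fraction <= 1:
        raise ValueError("min_qc_fraction must be in (0, 1]")
    n_qc = int(t.is_qc.sum())
    if n_qc == 0:
        raise FeatureTableError(
            "no QC samples in table; skip the QC-based filters explicitly"
        )
    present = t.presence_mask().loc[t.is_qc.to_numpy()]
    keep = present.sum(axis=0) / n_qc >= min_qc_fraction
    return _filtered(t, keep, "qc_presence")


def qc_cv_filter(
    t: FeatureTable, max_cv: float = 0.20
) -> tuple[FeatureTable, QaFilterLog]:
    """Keep features whose QC coefficient of variation is strictly < ``max_cv``.

    CV = sd/mean over the non-missing raw-scale QC intensities, with the
    n-1 standard deviation.  Features with fewer than two non-missing QC
    values (CV undefined) are removed, not errors.
    """
    if int(t.is_qc.sum()) == 0:
        raise FeatureTableError(
            "no QC samples in table; skip the QC-based filters explicitly"
        )
    qc = t.qc_intensities()
    n_obs = qc.notna().sum(axis=0)
    mean = qc.mean(axis=0)
    sd = qc.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = sd / mean
    keep = (n_obs >= 2) & (cv < max_cv)
    return _filtered(t, keep.fillna(False), "qc_cv")


def group_presence_filter(
    t: FeatureTable, min_group_fraction: float = 0.8
) -> tuple[FeatureTable, QaFilterLog]:
    """Keep features present in >= ``min_group_fraction`` of at least one group."""
    present = t.presence_mask().loc[(~t.is_qc).to_numpy()]
    labels = t.study_labels()
    keep = pd.Series(False, index=t.intensities.columns)
    for g in t.study_groups:
        sub = present.loc[(labels == g).to_numpy()]
        keep |= sub.sum(axis=0) / len(sub) >= min_group_fraction
    return _filtered(t, keep, "group_presence")


def apply_qa_pipeline(
    t: FeatureTable,
    min_qc_fraction: float = 0.5,
    max_cv: float = 0.20,
    min_group_fraction: float = 0.8,
) -> tuple[FeatureTable, list[QaFilterLog]]:
    """QC presence, then QC CV, then group presence — the full QA cascade."""
    t1, log1 = qc_presence_filter(t, min_qc_fraction)
    t2, log2 = qc_cv_filter(t1, max_cv)
    t3, log3 = group_presence_filter(t2, min_group_fraction)
    return t3, [log1, log2, log3]


# ----------------------------------------------------------------------
# Imputation
# ----------------------------------------------------------------------
def impute_half_min(t: FeatureTable) -> tuple[FeatureTable, pd.DataFrame]:
    """Impute missing cells with half the feature's minimum observed value.

    The limit-of-detection convention for left-censored LC-MS intensities.
    Returns the imputed table and the boolean mask of imputed cells, so the
    step is reversible (re-mask to recover the original missingness).
    """
    X = t.intensities.copy()
    mask = X.isna()
    fill = X.min(axis=0, skipna=True) / 2.0
    if mask.to_numpy().any() and fill.isna().any():
        bad = fill.index[fill.isna()].tolist()
        warnings.warn(f"features with no observed values left unimputed: {bad}")
    X = X.fillna(fill)
    imputed = FeatureTable(
        X, t.feature_meta.copy(), t.sample_meta.copy(), log_scale=t.log_scale
    )
    return imputed, mask
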