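"""Core data containers, CSV I/O and data-cleaning rules for c-Fos count tables.

The central object is :class:`ActivityDataset`: one row per subject (rat), one
column per sampled brain region, holding c-Fos+ cell counts averaged over
replicate 250 x 250 um ROIs.  Missing entries (damaged sections, unusable ROIs)
are NaN and tracked explicitly.  Cleaning follows two rules used throughout the
pipeline: a conservative two-clause outlier rule, and per-condition mean
imputation for methods that require complete data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Condition labels of the study design: two helping-behavior-test (HBT)
#: conditions, four social controls, a non-social reward control, the trapped
#: rats themselves, and a home-cage baseline.
CONDITION_LABELS = (
    "HBT_ingroup",
    "HBT_outgroup",
    "brief_ingroup",
    "brief_outgroup",
    "two_free_ingroup",
    "two_free_outgroup",
    "chocolate",
    "trapped",
    "baseline",
)

#: The six social conditions entering the task-PLS / ANOVA contrasts.
SOCIAL_CONDITIONS = (
    "HBT_ingroup",
    "HBT_outgroup",
    "brief_ingroup",
    "brief_outgroup",
    "two_free_ingroup",
    "two_free_outgroup",
)

#: Controlled vocabulary of anatomical groupings for region metadata.
REGION_CATEGORIES = (
    "frontal",
    "insular",
    "striatal",
    "hippocampal",
    "hypothalamic",
    "sensory",
    "other",
)


class DataValidationError(ValueError):
    """Raised when an input table violates a dataset invariant."""


@dataclass
class RegionInfo:
    """Metadata for one sampled brain region."""

    region_id: str
    full_name: str
    category: str
    ap_coordinate: float | None = None  # mm from Bregma

    def __post_init__(self) -> None:
        if self.category not in REGION_CATEGORIES:
            raise DataValidationError(
                f"unknown region category {self.category!r} for {self.region_id!r}; "
                f"expected one of {REGION_CATEGORIES}"
            )


@dataclass
class ActivityDataset:
    """Subject x region c-Fos count matrix with condition labels.

    Parameters
    ----------
    counts
        DataFrame indexed by subject id, one column per region id; NaN marks
        missing values.  Non-missing entries must be >= 0.
    conditions
        Series mapping subject id -> condition label (one of
        :data:`CONDITION_LABELS`).
    regions
        Optional region metadata table indexed by region_id with columns
        ``full_name``, ``category``, ``ap_mm``.
    """

    counts: pd.DataFrame
    conditions: pd.Series
    regions: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(float)
        self.conditions = self.conditions.reindex(self.counts.index)
        if self.conditions.isna().any():
            missing = list(self.conditions.index[self.conditions.isna()])
            raise DataValidationError(f"subjects without a condition label: {missing}")
        bad = set(self.conditions.unique()) - set(CONDITION_LABELS)
        if bad:
            raise DataValidationError(f"unknown condition labels: {sorted(bad)}")
        if self.counts.index.has_duplicates:
            dups = list(self.counts.index[self.counts.index.duplicated()])
            raise DataValidationError(f"duplicate subject ids: {dups}")
        neg = self.counts.lt(0)
        if neg.any().any():
            subj, reg = next(
                (s, r) for s in neg.index for r in neg.columns if neg.at[s, r]
            )
            raise DataValidationError(
                f"negative count for subject {subj!r}, region {reg!r}"
            )
        if self.regions is not None:
            unknown = set(self.counts.columns) - set(self.regions.index)
            if unknown:
                raise DataValidationError(
                    f"regions absent from metadata: {sorted(unknown)}"
                )

    # -- basic views ---------------------------------------------------------

    @property
    def subjects(self) -> list[str]:
        return list(self.counts.index)

    @property
    def region_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.counts.isna()

    @property
    def n_missing(self) -> int:
        return int(self.counts.isna().to_numpy().sum())

    def subset(self, conditions: list[str] | tuple[str, ...]) -> "ActivityDataset":
        """Restrict to subjects whose condition is in *conditions*."""
        keep = self.conditions.isin(list(conditions))
        return ActivityDataset(
            self.counts.loc[keep].copy(), self.conditions.loc[keep].copy(), self.regions
        )

    def copy(self) -> "ActivityDataset":
        return ActivityDataset(
            self.counts.copy(),
            self.conditions.copy(),
            None if self.regions is None else self.regions.copy(),
        )


@dataclass
class OutlierReport:
    """Record of values removed by :func:`remove_outliers`."""

    entries: list[dict] = field(default_factory=list)
    skipped_cells: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        cols = [
            "subject",
            "region",
            "value",
            "group_mean",
            "group_sd",
            "other_min",
            "other_max",
        ]
        return pd.DataFrame(self.entries, columns=cols)


# ---------------------------------------------------------------------------
# I/O


def load_regions(regions_path) -> pd.DataFrame:
    """Read a region-metadata CSV (region_id, full_name, category, ap_mm)."""
    meta = pd.read_csv(regions_path)
    required = {"region_id", "full_name", "category"}
    if not required.issubset(meta.columns):
        raise DataValidationError(
            f"region metadata must have columns {sorted(required)}"
        )
    if meta["region_id"].duplicated().any():
        raise DataValidationError("duplicate region_id in metadata")
    bad = set(meta["category"]) - set(REGION_CATEGORIES)
    if bad:
        raise DataValidationError(f"unknown region categories: {sorted(bad)}")
    if "ap_mm" not in meta.columns:
        meta["ap_mm"] = np.nan
    return meta.set_index("region_id")


def load_activity(counts_path, regions_path=None) -> ActivityDataset:
    """Load a c-Fos count table (and optional region metadata) from CSV.

    The counts CSV has columns ``subject_id``, ``condition``, then one column
    per region id; blank cells denote missing values.
    """
    table = pd.read_csv(counts_path)
    for col in ("subject_id", "condition"):
        if col not in table.columns:
            raise DataValidationError(f"counts file lacks required column {col!r}")
    if table["subject_id"].duplicated().any():
        dups = list(table.loc[table["subject_id"].duplicated(), "subject_id"])
        raise DataValidationError(f"duplicate subject ids: {dups}")
    table = table.set_index("subject_id")
    conditions = table.pop("condition").astype(str)
    regions = load_regions(regions_path) if regions_path is not None else None
    ds = ActivityDataset(table, conditions, regions)
    logger.info(
        "loaded activity table: %d subjects x %d regions, %d missing",
        len(ds.subjects), len(ds.region_ids), ds.n_missing,
    )
    return ds


def save_activity(ds: ActivityDataset, counts_path) -> None:
    """Write the counts table in the same dialect :func:`load_activity` reads."""
    out = ds.counts.copy()
    out.insert(0, "condition", ds.conditions)
    out.index.name = "subject_id"
    out.to_csv(counts_path)
    logger.info("wrote %d rows to %s", len(out), counts_path)


# ---------------------------------------------------------------------------
# Cleaning rules


def remove_outliers(ds: ActivityDataset) -> tuple[ActivityDataset, OutlierReport]:
    """Remove extreme counts by the two-clause rule, single pass.

    A value is flagged iff BOTH
      (a) it is more than 2 group standard deviations from its own
          (condition, region) mean, and
      (b) it lies strictly outside the observed [min, max] of that region's
          values pooled over all OTHER conditions.
    Group statistics are computed on the original data (no iteration).  Cells
    with fewer than 2 non-missing values have no SD and are never flagged.
    """
    report = OutlierReport()
    counts = ds.counts
    cleaned = counts.copy()
    cond = ds.conditions
    for region in counts.columns:
        col = counts[region]
        for c in cond.unique():
            vals = col[cond == c].dropna()
            if len(vals) < 2:
                report.skipped_cells.append((c, region))
                continue
            m, sd = vals.mean(), vals.std(ddof=1)
            others = col[cond != c].dropna()
            if others.empty:
                continue
            lo, hi = others.min(), others.max()
            for subj, v in vals.items():
                if abs(v - m) > 2 * sd and (v < lo or v > hi):
                    cleaned.at[subj, region] = np.nan
                    report.entries.append(
                        dict(
                            subject=subj, region=region, value=v,
                            group_mean=m, group_sd=sd,
                            other_min=lo, other_max=hi,
                        )
                    )
    logger.info("outlier removal: %d values removed", report.n_removed)
    return ActivityDataset(cleaned, cond.copy(), ds.regions), report


def impute_condition_mean(ds: ActivityDataset) -> ActivityDataset:
    """Replace missing entries by the mean of their (condition, region) cell.

    Non-missing entries are unchanged; the result has no missing values.
    Raises if any (condition, region) cell is entirely missing.
    """
    if ds.n_missing == 0:
        return ds.copy()
    counts = ds.counts.copy()
    for c, block in counts.groupby(ds.conditions):
        means = block.mean()
        empty = means.index[means.isna() & block.isna().any()]
        if len(empty):
            raise DataValidationError(
                f"cannot impute: condition {c!r}, region {empty[0]!r} entirely missing"
            )
        counts.loc[block.index] = block.fillna(means)
    return ActivityDataset(counts, ds.conditions.copy(), ds.regions)


def condition_totals(ds: ActivityDataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject total c-Fos (missing ignored) and per-condition mean +/- SEM.

    Returns ``(per_subject, per_condition)`` where ``per_subject`` has columns
    condition, total and ``per_condition`` has columns mean, sem, n.
    """
    totals = ds.counts.sum(axis=1, skipna=True)
    per_subject = pd.DataFrame({"condition": ds.conditions, "total": totals})
    grouped = per_subject.groupby("condition")["total"]
    per_condition = grouped.agg(["mean", "sem", "count"]).rename(
        columns={"count": "n"}
    )
    return per_subject, per_condition
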