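"""Retrograde-tracing co-label quantification and behavioral correlations.

Fluoro-Gold (FG) injected in the nucleus accumbens back-labels projection
neurons; FG+/c-Fos+ co-labeled cells are task-active neurons projecting to
the Nac.  This module computes per-region co-label fractions, their Pearson
correlation with door-opening behavior (with raw c-Fos counts as the
negative control), and the opener vs non-opener group comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import TestResult, correct_pvalues, pearson, ttest_two_sample

logger = logging.getLogger(__name__)


@dataclass
class TracingDataset:
    """Per-(rat, region) FG/c-Fos counts plus per-rat behavior."""

    cells: pd.DataFrame     # columns rat_id, region_id, fg_count, cfos_count, colabel_count
    behavior: pd.DataFrame  # index rat_id; columns pct_door_openings, opener

    def __post_init__(self) -> None:
        c = self.cells
        for col in ("fg_count", "cfos_count", "colabel_count"):
            if (c[col] < 0).any():
                raise ValueError(f"negative {col}")
        bad = c["colabel_count"] > np.minimum(c["fg_count"], c["cfos_count"])
        if bad.any():
            row = c[bad].iloc[0]
            raise ValueError(
                f"colabel exceeds min(fg, cfos) for rat {row['rat_id']!r}, "
                f"region {row['region_id']!r}"
            )
        if not ((self.behavior["pct_door_openings"] >= 0)
                & (self.behavior["pct_door_openings"] <= 100)).all():
            raise ValueError("pct_door_openings outside [0, 100]")

    @property
    def regions(self) -> list[str]:
        return sorted(self.cells["region_id"].unique())


def load_tracing(cells_path, behavior_path) -> TracingDataset:
    cells = pd.read_csv(cells_path)
    behavior = pd.read_csv(behavior_path).set_index("rat_id")
    return TracingDataset(cells, behavior)


def colabel_fraction(ds: TracingDataset) -> pd.DataFrame:
    """Percent of FG+ cells co-labeled with c-Fos per (rat, region).

    Cells with fg_count = 0 carry no information about the fraction and are
    excluded (logged), not reported as 0%.
    """
    c = ds.cells.copy()
    zero = c["fg_count"] == 0
    if zero.any():
        logger.info("colabel fraction: excluded %d rows with fg_count = 0",
                    int(zero.sum()))
    c = c[~zero].copy()
    c["pct_colabel"] = 100.0 * c["colabel_count"] / c["fg_count"]
    return c[["rat_id", "region_id", "pct_colabel"]]


def behavior_correlation(
    ds: TracingDataset, region: str, measure: str = "pct_colabel"
) -> TestResult:
    """Pearson correlation of a region's measure with % door-openings.

    ``measure`` is "pct_colabel" (co-label fraction, the projection-specific
    readout) or "cfos_count" (raw activity, the negative control).
    """
    if measure == "pct_colabel":
        table = colabel_fraction(ds)
        sub = table[table["region_id"] == region].set_index("rat_id")["pct_colabel"]
    elif measure == "cfos_count":
        c = ds.cells
        sub = c[c["region_id"] == region].set_index("rat_id")["cfos_count"]
    else:
        raise ValueError(f"unknown measure {measure!r}")
    joined = pd.concat(
        [sub, ds.behavior["pct_door_openings"]], axis=1, join="inner"
    ).dropna()
    if len(joined) < 4:
        raise ValueError(f"need >= 4 rats with data for region {region!r}")
    return pearson(joined.iloc[:, 0], joined["pct_door_openings"])


def opener_group_comparison(
    ds: TracingDataset, measure: str = "cfos_count"
) -> dict:
    """Opener vs non-opener comparison across regions (cell-means model).

    The global group main effect is the two-way ANOVA F for opener status
    with region as the stratifying factor, F(1, N - 2g) on the cell-means
    residual; per-region contrasts are t tests with Sidak correction over
    regions.  ``measure`` in {"cfos_count", "fg_count", "pct_colabel"}.
    """
    if measure == "pct_colabel":
        table = colabel_fraction(ds).rename(columns={"pct_colabel": "value"})
    else:
        table = ds.cells[["rat_id", "region_id", measure]].rename(
            columns={measure: "value"}
        )
    table = table.merge(
        ds.behavior["opener"].rename("opener"), left_on="rat_id", right_index=True
    )
    groups = table.groupby("opener")
    if len(groups) < 2:
        raise ValueError("need both openers and non-openers")
    regions = sorted(table["region_id"].unique())
    g_cells = len(regions)

    # cell-means ANOVA: residual SS within (opener x region) cells
    cell_means = table.groupby(["opener", "region_id"])["value"].transform("mean")
    ss_resid = float(((table["value"] - cell_means) ** 2).sum())
    df_resid = len(table) - 2 * g_cells
    # group main effect: unweighted marginal means over region cells
    marg = table.groupby(["opener", "region_id"])["value"].mean().unstack()
    effect = marg.mean(axis=1)
    n_cell = table.groupby(["opener", "region_id"])["value"].count().unstack()
    # harmonic-mean cell size (unweighted-means solution for unbalanced data)
    nh = 1.0 / np.mean(1.0 / n_cell.to_numpy())
    grand = effect.mean()
    ss_group = nh * g_cells * float(((effect - grand) ** 2).sum())
    ms_group = ss_group / 1.0
    ms_resid = ss_resid / df_resid
    F = ms_group / ms_resid
    p = float(sps.f.sf(F, 1, df_resid))
    main_effect = TestResult(
        "opener_main_effect_F", float(F), (1, df_resid), p, len(table),
        {"group_means": {str(k): float(v) for k, v in effect.items()}},
    )

    contrasts = []
    for region in regions:
        sub = table[table["region_id"] == region]
        a = sub.loc[sub["opener"].astype(bool), "value"].to_numpy()
        b = sub.loc[~sub["opener"].astype(bool), "value"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            contrasts.append({"region": region, "t": np.nan, "p_raw": np.nan})
            continue
        try:
            t = ttest_two_sample(a, b)
            contrasts.append({"region": region, "t": t.statistic, "p_raw": t.p_value})
        except ValueError:
            contrasts.append({"region": region, "t": np.nan, "p_raw": np.nan})
    ct = pd.DataFrame(contrasts).set_index("region")
    valid = ct["p_raw"].notna()
    sidak = np.full(len(ct), np.nan)
    sidak[valid.to_numpy()] = correct_pvalues(
        ct.loc[valid, "p_raw"].to_numpy(), "sidak"
    )
    ct["p_sidak"] = sidak
    ct["significant"] = ct["p_sidak"] < 0.05
    return {"main_effect": main_effect, "contrasts": ct, "measure": measure}
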