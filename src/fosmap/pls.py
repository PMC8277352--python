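"""Mean-centered task partial least squares (PLS) over conditions.

Task PLS contrasts condition-mean c-Fos profiles: the condition x region
matrix of condition means, column-centered by the unweighted grand mean of
condition means, is decomposed by SVD into mutually orthogonal latent
variables (LVs).  Each LV pairs a condition contrast (left singular vector)
with a region salience profile (right singular vector), scaled by its singular
value.  LV significance is assessed by permutation of subject->condition
assignments (group sizes fixed); salience reliability by bootstrap resampling
of subjects within condition, with each bootstrap solution aligned to the
observed one by an orthogonal Procrustes rotation before the standard error is
taken.  Regions with |salience / bootstrap SE| above 2.57 (the two-sided 99%
normal quantile) are treated as reliably contributing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import svd

from .data import ActivityDataset

logger = logging.getLogger(__name__)

#: round(Phi^{-1}(0.995), 2): bootstrap-ratio cutoff ~ two-sided 99% CI.
BOOTSTRAP_RATIO_99 = 2.57


@dataclass
class PLSResult:
    """Latent variables of a task-PLS decomposition."""

    conditions: list[str]
    regions: list[str]
    singular_values: np.ndarray          # (n_lv,), descending
    condition_saliences: pd.DataFrame    # condition x LV
    region_saliences: pd.DataFrame       # region x LV
    permutation_p: np.ndarray            # (n_lv,)
    bootstrap_ratios: pd.DataFrame       # region x LV
    bootstrap_se: pd.DataFrame           # region x LV
    n_perm: int
    n_boot: int
    seed: int

    @property
    def n_lv(self) -> int:
        return len(self.singular_values)

    def to_records(self) -> list[dict]:
        return [
            {
                "lv": i + 1,
                "singular_value": float(self.singular_values[i]),
                "p": float(self.permutation_p[i]),
                "condition_saliences": {
                    c: float(self.condition_saliences.iloc[j, i])
                    for j, c in enumerate(self.conditions)
                },
            }
            for i in range(self.n_lv)
        ]


def build_centered_condition_matrix(
    ds: ActivityDataset, conditions: list[str] | tuple[str, ...]
) -> pd.DataFrame:
    """Condition-mean matrix, column-centered by the unweighted grand mean.

    Requires complete (imputed) data.  Every column of the result sums to
    zero across conditions.
    """
    if ds.n_missing:
        raise ValueError("PLS requires imputed data (missing values present)")
    conditions = list(conditions)
    if len(conditions) < 2:
        raise ValueError("need >= 2 conditions")
    rows = {}
    for c in conditions:
        subj = ds.conditions.index[ds.conditions == c]
        if len(subj) == 0:
            raise ValueError(f"condition {c!r} has no subjects")
        rows[c] = ds.counts.loc[subj].mean(axis=0)
    M = pd.DataFrame(rows).T.loc[conditions]
    return M - M.mean(axis=0)


def _svd_of(ds: ActivityDataset, conditions: list[str]):
    M = build_centered_condition_matrix(ds, conditions)
    U, s, Vt = svd(M.to_numpy(), full_matrices=False)
    return M, U, s, Vt.T


def _procrustes_rotation(V_boot: np.ndarray, V_obs: np.ndarray) -> np.ndarray:
    """Orthogonal rotation Q minimizing ||V_boot @ Q - V_obs||_F."""
    U, _, Wt = svd(V_boot.T @ V_obs, full_matrices=False)
    return U @ Wt


def run_task_pls(
    ds: ActivityDataset,
    conditions: list[str] | tuple[str, ...],
    n_perm: int = 500,
    n_boot: int = 500,
    seed: int = 0,
) -> PLSResult:
    """Task PLS with permutation testing of LVs and bootstrap salience SEs.

    Permutation: subject condition labels are shuffled without replacement
    (group sizes preserved) and the full pipeline recomputed; the p value for
    LV k is (#{permuted s_k >= observed s_k} + 1) / (n_perm + 1).

    Bootstrap: subjects are resampled with replacement within their condition
    (assignments kept); each bootstrap region-salience matrix is aligned to
    the observed one by Procrustes rotation, and the bootstrap ratio is
    observed salience / SE over the aligned bootstrap distribution.
    """
    if n_perm < 1 or n_boot < 1:
        raise ValueError("n_perm and n_boot must be >= 1")
    conditions = list(conditions)
    rng = np.random.default_rng(seed)
    sub = ds.subset(conditions)
    M, U, s, V = _svd_of(sub, conditions)
    n_lv = len(s)

    labels = sub.conditions.copy()
    counts = sub.counts

    # permutation test of singular values
    exceed = np.zeros(n_lv)
    lab_values = labels.to_numpy()
    for _ in range(n_perm):
        perm = rng.permutation(len(lab_values))
        perm_labels = pd.Series(lab_values[perm], index=labels.index)
        perm_ds = ActivityDataset(counts, perm_labels, sub.regions)
        _, _, s_p, _ = _svd_of(perm_ds, conditions)
        exceed += s_p[:n_lv] >= s
    perm_p = (exceed + 1.0) / (n_perm + 1.0)

    # bootstrap of region saliences, Procrustes-aligned
    by_cond = {c: labels.index[labels == c] for c in conditions}
    boot_V = np.empty((n_boot, *V.shape))
    b = 0
    n_redraws = 0
    while b < n_boot:
        idx = []
        ok = True
        for c in conditions:
            pool = by_cond[c]
            draw = rng.choice(pool, size=len(pool), replace=True)
            # resample must retain >= 2 distinct subjects where the pool allows
            if len(pool) >= 2 and len(set(draw)) < 2:
                ok = False
                break
            idx.extend(draw)
        if not ok:
            n_redraws += 1
            continue
        boot_counts = counts.loc[idx].reset_index(drop=True)
        boot_labels = pd.Series(
            np.concatenate([[c] * len(by_cond[c]) for c in conditions]),
            index=boot_counts.index,
        )
        boot_ds = ActivityDataset(boot_counts, boot_labels, None)
        Mb = build_centered_condition_matrix(boot_ds, conditions)
        if not np.isfinite(Mb.to_numpy()).all():
            n_redraws += 1
            continue
        _, sb, Vbt = np.linalg.svd(Mb.to_numpy(), full_matrices=False)
        Vb = Vbt.T
        Q = _procrustes_rotation(Vb * sb, V * s)
        boot_V[b] = (Vb * sb) @ Q
        b += 1
    if n_redraws:
        logger.info("bootstrap: %d resamples redrawn", n_redraws)

    se = boot_V.std(axis=0, ddof=1)
    saliences = V * s  # singular-value-scaled saliences
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(se > 0, saliences / se, np.inf * np.sign(saliences))

    regions = list(M.columns)
    lv_names = [f"LV{i+1}" for i in range(n_lv)]
    return PLSResult(
        conditions=conditions,
        regions=regions,
        singular_values=s,
        condition_saliences=pd.DataFrame(U, index=conditions, columns=lv_names),
        region_saliences=pd.DataFrame(V, index=regions, columns=lv_names),
        permutation_p=perm_p,
        bootstrap_ratios=pd.DataFrame(ratios, index=regions, columns=lv_names),
        bootstrap_se=pd.DataFrame(se, index=regions, columns=lv_names),
        n_perm=n_perm,
        n_boot=n_boot,
        seed=seed,
    )


def reliable_regions(
    result: PLSResult, lv: int = 1, threshold: float = BOOTSTRAP_RATIO_99
) -> dict[str, list[str]]:
    """Regions with |bootstrap ratio| > *threshold* on LV *lv* (1-based),
    partitioned by salience sign."""
    col = f"LV{lv}"
    ratios = result.bootstrap_ratios[col]
    pos = [r for r in result.regions if ratios[r] > threshold]
    neg = [r for r in result.regions if ratios[r] < -threshold]
    return {"positive": pos, "negative": neg}
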