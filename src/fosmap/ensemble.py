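"""Ensemble eigen-region classification of condition-specific brain regions.

Because a single co-activation network depends on arbitrary choices
(threshold, clustering algorithm, edge weighting, reference group), regions
that matter specifically for the helping-test ingroup condition are identified
by an ensemble: 40 configurations (5 thresholds x 2 clusterings x 2
weightings x 2 references) are each run end to end --

  cluster regions on pooled counts -> take each cluster's first principal
  component across subjects (its "eigen region") -> multinomial logistic
  regression of condition (ingroup / outgroup / reference) on the eigen
  region -> Bonferroni-corrected Wald tests classify each cluster as
  significant for the ingroup only, the outgroup only, both, or neither --

and every region inherits its cluster's classification.  Tallying over the 40
configurations gives per-region occurrence ratios; a high ingroup-only ratio
marks a region as uniquely important for the ingroup condition.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .data import ActivityDataset
from .network import (
    correlation_matrix,
    louvain_communities,
    scale_free_index,
    threshold_network,
)

logger = logging.getLogger(__name__)

CATEGORIES = ("ingroup_only", "outgroup_only", "both", "none")

#: Conditions forming the broad reference group (untested-condition pool).
BROAD_REFERENCE = (
    "brief_ingroup",
    "brief_outgroup",
    "two_free_ingroup",
    "two_free_outgroup",
    "trapped",
    "baseline",
)

DEFAULT_THRESHOLDS = (0.05, 0.10, 0.15, 0.20, 0.25)


@dataclass(frozen=True)
class EnsembleConfig:
    config_id: str
    threshold_frac: float
    clustering: str          # "louvain" | "dynamic_tree_cut"
    weighting: str           # "binary" | "soft_power"
    reference: str           # "baseline_only" | "broad_reference"
    soft_power_beta: float | str = "auto"
    seed: int = 0


@dataclass
class EnsembleTally:
    """Per-region occurrence counts over the configurations."""

    counts: pd.DataFrame     # region x CATEGORIES
    n_configs: int
    per_config: list = field(default_factory=list)

    @property
    def ratios(self) -> pd.DataFrame:
        return 100.0 * self.counts / self.n_configs

    def ratio_ingroup_only(self, region: str) -> float:
        return float(self.ratios.loc[region, "ingroup_only"])

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        for cat in CATEGORIES:
            out[f"pct_{cat}"] = 100.0 * out[cat] / self.n_configs
        return out


def default_config_grid(seed: int = 0) -> list[EnsembleConfig]:
    """The full-factorial 5 x 2 x 2 x 2 = 40 configuration grid."""
    configs = []
    for frac, clust, weight, ref in itertools.product(
        DEFAULT_THRESHOLDS,
        ("louvain", "dynamic_tree_cut"),
        ("binary", "soft_power"),
        ("baseline_only", "broad_reference"),
    ):
        cid = (
            f"t{int(round(frac * 100)):02d}-{clust}-{weight}-"
            f"{'base' if ref == 'baseline_only' else 'broad'}"
        )
        configs.append(
            EnsembleConfig(cid, frac, clust, weight, ref, "auto", seed)
        )
    return configs


def soft_power_adjacency(
    r_matrix: pd.DataFrame, beta="auto", target_sfi: float = 0.8
) -> tuple[pd.DataFrame, float]:
    """WGCNA-style soft-power adjacency a_ij = |r_ij|^beta.

    ``beta="auto"`` picks the smallest integer beta in [1, 20] whose weighted
    connectivity profile has a scale-free fit index >= *target_sfi*; if none
    qualifies, beta = 6 (the WGCNA default for signed-absolute networks) with
    a log message.
    """
    absr = r_matrix.abs().fillna(0.0)
    np.fill_diagonal(absr.values, 0.0)
    if beta == "auto":
        chosen = None
        for b in range(1, 21):
            a = absr**b
            k = a.sum(axis=1).to_numpy()
            sfi, _ = scale_free_index(k)
            if sfi is not None and sfi >= target_sfi:
                chosen = b
                break
        if chosen is None:
            chosen = 6
            logger.info("soft power auto-selection failed; falling back to beta=6")
        beta = chosen
    beta = float(beta)
    return absr**beta, beta


def _dynamic_tree_cut(
    dissim: pd.DataFrame, min_cluster_size: int = 3, cut_height_frac: float = 0.99
) -> dict[str, int]:
    """Simplified dynamic-hybrid branch cut of an average-linkage dendrogram.

    Cuts the tree at *cut_height_frac* of the maximum merge height, then
    enforces the minimum cluster size: members of undersized branches are
    reassigned to the nearest surviving cluster (by mean dissimilarity) when
    one is closer than the cut height, otherwise they fall into the
    "unclustered" pseudo-cluster (id -1), which is excluded from regression.
    """
    regions = list(dissim.index)
    if len(regions) < 3:
        raise ValueError("need >= 3 regions")
    condensed = squareform(dissim.to_numpy(), checks=False)
    Z = linkage(condensed, method="average")
    cut = cut_height_frac * Z[:, 2].max() if Z[:, 2].max() > 0 else 0.0
    labels = fcluster(Z, t=cut, criterion="distance")
    assign = dict(zip(regions, labels))
    sizes = pd.Series(labels).value_counts()
    keep = set(sizes.index[sizes >= min_cluster_size])
    out = {}
    for region in regions:
        lab = assign[region]
        if lab in keep:
            out[region] = int(lab)
            continue
        # try to attach to the nearest surviving cluster
        best, best_d = None, np.inf
        for k in keep:
            members = [r for r in regions if assign[r] == k]
            d = float(dissim.loc[region, members].mean())
            if d < best_d:
                best, best_d = k, d
        if best is not None and best_d <= cut:
            out[region] = int(best)
        else:
            out[region] = -1
    # relabel to consecutive ids, keep -1 for unclustered
    ids = sorted({v for v in out.values() if v != -1})
    remap = {old: new for new, old in enumerate(ids)}
    return {r: (remap[v] if v != -1 else -1) for r, v in out.items()}


def cluster_regions(
    ds: ActivityDataset, config: EnsembleConfig, conditions: list[str]
) -> dict[str, int]:
    """Partition regions under one ensemble configuration.

    Correlation structure is computed on counts pooled over the compared and
    reference conditions (the partition must be condition-agnostic so every
    subject gets a cluster score).  The threshold selects the top
    ``threshold_frac`` pairs by |r|; retained pairs carry weight 1 (binary) or
    |r|^beta (soft power).  Clusters with fewer than 3 regions are merged or
    marked unclustered (-1).
    """
    sub = ds.subset(conditions)
    if len(sub.region_ids) < 3:
        raise ValueError("need >= 3 regions")
    r, _ = correlation_matrix(sub)
    if config.weighting == "soft_power":
        a, beta = soft_power_adjacency(r, config.soft_power_beta)
        strength = a
    elif config.weighting == "binary":
        strength = r.abs().fillna(0.0)
        np.fill_diagonal(strength.values, 0.0)
    else:
        raise ValueError(f"unknown weighting {config.weighting!r}")

    net = threshold_network(r, config.threshold_frac)
    retained = net.adjacency.astype(bool)

    if config.clustering == "louvain":
        G = net.graph.copy()
        for u, v in G.edges:
            G[u][v]["weight"] = float(strength.loc[u, v])
        clusters = louvain_communities(G, seed=config.seed)
        # enforce minimum size 3 by marking small communities unclustered
        sizes = pd.Series(clusters).value_counts()
        small = set(sizes.index[sizes < 3])
        clusters = {r_: (-1 if c in small else c) for r_, c in clusters.items()}
        ids = sorted({v for v in clusters.values() if v != -1})
        remap = {old: new for new, old in enumerate(ids)}
        return {r_: (remap[v] if v != -1 else -1) for r_, v in clusters.items()}
    if config.clustering == "dynamic_tree_cut":
        sim = strength.where(retained, 0.0)
        sim = sim / max(float(sim.max().max()), 1e-12)
        dissim = 1.0 - sim
        np.fill_diagonal(dissim.values, 0.0)
        return _dynamic_tree_cut(dissim)
    raise ValueError(f"unknown clustering {config.clustering!r}")


def eigen_regions(
    ds: ActivityDataset, clusters: dict[str, int]
) -> pd.DataFrame:
    """Subject x cluster matrix of first-principal-component ("eigen region")
    scores.

    Regions are z-scored across subjects; per cluster the first PC score of
    the subjects is taken, sign-fixed to correlate positively with the
    cluster's mean z profile.  Singleton clusters pass their z-scored values
    through; zero-variance regions are dropped with a warning.  Unclustered
    regions (id -1) are skipped.
    """
    if ds.n_missing:
        raise ValueError("eigen regions require complete (imputed) data")
    counts = ds.counts
    scores = {}
    for cid in sorted({c for c in clusters.values() if c != -1}):
        members = [r for r, c in clusters.items() if c == cid]
        block = counts[members]
        sd = block.std(ddof=1)
        dead = list(sd.index[sd == 0])
        if dead:
            logger.warning("zero-variance regions dropped from cluster %d: %s",
                           cid, dead)
            members = [m for m in members if m not in dead]
        if not members:
            continue
        Z = (block[members] - block[members].mean()) / block[members].std(ddof=1)
        z = Z.to_numpy()
        if len(members) == 1:
            sc = z[:, 0]
        else:
            U, s, _ = np.linalg.svd(z, full_matrices=False)
            sc = U[:, 0] * s[0]
            profile = z.mean(axis=1)
            if np.dot(sc - sc.mean(), profile - profile.mean()) < 0:
                sc = -sc
        scores[cid] = sc
    return pd.DataFrame(scores, index=counts.index)


# ---------------------------------------------------------------------------
# Ridge-stabilized multinomial logistic regression (3 outcome classes)


def _fit_multinomial(
    x: np.ndarray,
    y: np.ndarray,
    ridge: float = 1e-4,
    max_iter: int = 100,
    fix_zero: int | None = None,
):
    """Newton fit of a 3-class multinomial logit with one predictor.

    y codes classes 0 (reference), 1, 2.  A small ridge penalty on all
    coefficients guards against perfect separation; Wald SEs come from the
    penalized observed information.  ``fix_zero`` (0 or 1) constrains that
    non-reference class's slope to zero (the profile fit used by the
    likelihood-ratio test).  Returns (coefs (2, 2), se (2, 2), loglik,
    converged) with coef rows = non-reference classes, columns = (intercept,
    slope).
    """
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    Y = np.zeros((n, 2))
    for c in (1, 2):
        Y[:, c - 1] = y == c
    free = np.ones(4, dtype=bool)   # [b1_0, b1_x, b2_0, b2_x]
    if fix_zero is not None:
        free[2 * fix_zero + 1] = False
    theta = np.zeros(4)
    converged = False
    H = -np.eye(4)
    for _ in range(max_iter):
        B = theta.reshape(2, 2)
        eta = np.clip(X @ B.T, -500, 500)   # (n, 2)
        denom = 1.0 + np.exp(eta).sum(axis=1)
        P = np.exp(eta) / denom[:, None]    # (n, 2)
        grad = np.concatenate([X.T @ (Y[:, c] - P[:, c]) for c in range(2)])
        grad -= ridge * theta
        H = np.zeros((4, 4))
        for c in range(2):
            for d in range(2):
                w = P[:, c] * ((c == d) - P[:, d])
                H[2 * c: 2 * c + 2, 2 * d: 2 * d + 2] = -(X * w[:, None]).T @ X
        H -= ridge * np.eye(4)
        try:
            step = np.linalg.solve(H[np.ix_(free, free)], grad[free])
        except np.linalg.LinAlgError:
            return None, None, np.nan, False
        theta[free] = theta[free] - step
        if np.max(np.abs(step)) < 1e-8:
            converged = True
            break
    if not np.isfinite(theta).all():
        return None, None, np.nan, False
    B = theta.reshape(2, 2)
    eta = np.clip(X @ B.T, -500, 500)
    denom = 1.0 + np.exp(eta).sum(axis=1)
    loglik = float((Y * eta).sum() - np.log(denom).sum())
    loglik -= 0.5 * ridge * float((theta**2).sum())
    cov = np.linalg.inv(-H)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return B, se.reshape(2, 2), loglik, converged


def multinomial_test(
    scores: pd.DataFrame,
    labels: pd.Series,
    alpha: float = 0.05,
    method: str = "lrt",
) -> pd.DataFrame:
    """Per-cluster multinomial logistic regression against the reference.

    *labels* maps subject -> {"ingroup", "outgroup", "reference"}.  One model
    per cluster (intercept + eigen-region predictor); per-contrast p values
    by profile likelihood-ratio test (default) or Wald; Bonferroni over
    clusters x 2 contrasts.  Wald inference is retained as an option but at
    the study's group sizes it suffers the Hauck-Donner collapse under
    near-separation (the Wald z shrinks as the effect grows), so the LRT is
    the default.  Returns a DataFrame indexed by cluster id with
    coef/p/significance columns (both p variants reported).
    """
    if method not in ("lrt", "wald"):
        raise ValueError("method must be 'lrt' or 'wald'")
    labels = labels.reindex(scores.index)
    if labels.isna().any():
        raise ValueError("labels missing for some subjects")
    class_code = labels.map({"reference": 0, "ingroup": 1, "outgroup": 2})
    if class_code.isna().any():
        raise ValueError("labels must be ingroup/outgroup/reference")
    counts = class_code.value_counts()
    if counts.min() < 3 or len(counts) < 3:
        raise ValueError("need >= 3 subjects in each outcome class")
    y = class_code.to_numpy(int)
    rows = []
    for cid in scores.columns:
        x = scores[cid].to_numpy(float)
        xs = (x - x.mean()) / (x.std(ddof=1) if x.std(ddof=1) > 0 else 1.0)
        coef, se, ll_full, ok = _fit_multinomial(xs, y)
        if not ok or coef is None:
            rows.append(
                dict(cluster=cid, coef_ingroup=np.nan, p_ingroup=np.nan,
                     p_wald_ingroup=np.nan, coef_outgroup=np.nan,
                     p_outgroup=np.nan, p_wald_outgroup=np.nan,
                     converged=False)
            )
            continue
        zvals = coef[:, 1] / np.where(se[:, 1] > 0, se[:, 1], np.inf)
        p_wald = 2.0 * sps.norm.sf(np.abs(zvals))
        p_lrt = np.full(2, np.nan)
        for c in range(2):
            _, _, ll_red, ok_red = _fit_multinomial(xs, y, fix_zero=c)
            if ok_red:
                stat = max(0.0, 2.0 * (ll_full - ll_red))
                p_lrt[c] = float(sps.chi2.sf(stat, 1))
        chosen = p_lrt if method == "lrt" else p_wald
        rows.append(
            dict(cluster=cid, coef_ingroup=coef[0, 1], p_ingroup=chosen[0],
                 p_wald_ingroup=p_wald[0], coef_outgroup=coef[1, 1],
                 p_outgroup=chosen[1], p_wald_outgroup=p_wald[1],
                 converged=True)
        )
    out = pd.DataFrame(rows).set_index("cluster")
    m = 2 * len(out)
    out["p_ingroup_bonf"] = np.minimum(1.0, out["p_ingroup"] * m)
    out["p_outgroup_bonf"] = np.minimum(1.0, out["p_outgroup"] * m)
    out["sig_ingroup"] = out["p_ingroup_bonf"] < alpha
    out["sig_outgroup"] = out["p_outgroup_bonf"] < alpha
    return out


def _classify(sig_in: bool, sig_out: bool) -> str:
    if sig_in and sig_out:
        return "both"
    if sig_in:
        return "ingroup_only"
    if sig_out:
        return "outgroup_only"
    return "none"


def run_ensemble(
    ds: ActivityDataset, configs: list[EnsembleConfig] | None = None,
    alpha: float = 0.05,
) -> EnsembleTally:
    """Run every configuration and tally per-region category occurrences.

    The dataset must contain both HBT conditions plus the reference
    conditions and be complete (imputed).  Non-converged clusters and
    unclustered regions count as "none".
    """
    if configs is None:
        configs = default_config_grid()
    if ds.n_missing:
        raise ValueError("run_ensemble requires imputed data")
    regions = ds.region_ids
    counts = pd.DataFrame(0, index=regions, columns=list(CATEGORIES))
    per_config = []
    for config in configs:
        if config.reference == "baseline_only":
            ref_conditions = ["baseline"]
        elif config.reference == "broad_reference":
            ref_conditions = list(BROAD_REFERENCE)
        else:
            raise ValueError(f"unknown reference {config.reference!r}")
        conditions = ["HBT_ingroup", "HBT_outgroup"] + ref_conditions
        present = [c for c in conditions if (ds.conditions == c).any()]
        if "HBT_ingroup" not in present or "HBT_outgroup" not in present:
            raise ValueError("dataset lacks an HBT condition")
        clusters = cluster_regions(ds, config, present)
        sub = ds.subset(present)
        scores = eigen_regions(sub, clusters)
        labels = sub.conditions.map(
            lambda c: "ingroup" if c == "HBT_ingroup"
            else ("outgroup" if c == "HBT_outgroup" else "reference")
        )
        if scores.shape[1] == 0:
            category = {r: "none" for r in regions}
        else:
            tests = multinomial_test(scores, labels, alpha=alpha)
            cluster_cat = {
                cid: _classify(bool(row["sig_ingroup"]), bool(row["sig_outgroup"]))
                if row["converged"]
                else "none"
                for cid, row in tests.iterrows()
            }
            category = {
                r: cluster_cat.get(clusters.get(r, -1), "none") for r in regions
            }
        for r in regions:
            counts.loc[r, category[r]] += 1
        per_config.append({"config_id": config.config_id, "category": category})
    return EnsembleTally(counts, len(configs), per_config)
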