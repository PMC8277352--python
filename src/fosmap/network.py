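"""Co-activation network inference from c-Fos counts.

Inter-region Pearson correlations across subjects of one condition define a
signed correlation matrix; retaining the top fraction of |r| pairs (default
10%) as unit-weight edges gives the co-activation graph.  The retention
fraction is chosen by sweeping thresholds and asking for scale-free degree
structure (WGCNA-style log-log fit index) without sacrificing connectivity or
small-worldness.  Hubs are regions in the top 20% of both degree and
betweenness; communities come from seeded Louvain modularity maximization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .data import ActivityDataset

logger = logging.getLogger(__name__)


@dataclass
class CoactivationNetwork:
    """Thresholded co-activation graph plus the full signed r matrix."""

    r_matrix: pd.DataFrame           # region x region Pearson r (NaN = invalid)
    n_matrix: pd.DataFrame           # pairwise n per cell
    threshold_frac: float
    graph: nx.Graph                  # binary edges; edge attr "r", "sign"
    condition: str = ""
    realized_frac: float = 0.0       # may exceed threshold_frac on ties

    @property
    def adjacency(self) -> pd.DataFrame:
        regions = list(self.r_matrix.index)
        A = pd.DataFrame(0, index=regions, columns=regions, dtype=int)
        for u, v in self.graph.edges:
            A.loc[u, v] = A.loc[v, u] = 1
        return A


@dataclass
class ThresholdSweep:
    table: pd.DataFrame              # threshold_frac ascending
    recommended: float | None = None


def correlation_matrix(
    ds: ActivityDataset, condition: str | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson r between regions for one condition.

    Returns (r, n) DataFrames; cells with pairwise n < 3 are NaN in r and
    excluded from downstream edge ranking.
    """
    sub = ds.subset([condition]) if condition is not None else ds
    if len(sub.subjects) < 3:
        raise ValueError("need >= 3 subjects for correlations")
    counts = sub.counts
    r = counts.corr(method="pearson", min_periods=3)
    present = counts.notna().astype(int)
    n = present.T @ present
    r.values[np.asarray(n) < 3] = np.nan
    np.fill_diagonal(r.values, 1.0)
    return r, n


def threshold_network(
    r_matrix: pd.DataFrame,
    threshold_frac: float = 0.10,
    n_matrix: pd.DataFrame | None = None,
    condition: str = "",
) -> CoactivationNetwork:
    """Keep the top *threshold_frac* of off-diagonal pairs ranked by |r|.

    Retained edges get unit weight; the sign of r is kept as an attribute
    (negative correlations are still edges).  Ties at the cutoff are all
    retained and the realized fraction logged.
    """
    if not (0 < threshold_frac <= 1):
        raise ValueError("threshold_frac must lie in (0, 1]")
    regions = list(r_matrix.index)
    pairs = []
    for i, u in enumerate(regions):
        for v in regions[i + 1:]:
            rv = r_matrix.loc[u, v]
            if np.isfinite(rv):
                pairs.append((abs(rv), rv, u, v))
    if not pairs:
        raise ValueError("no valid region pairs")
    pairs.sort(key=lambda t: -t[0])
    n_keep = round(threshold_frac * len(pairs))
    if n_keep < len(pairs):
        cut = pairs[n_keep - 1][0] if n_keep > 0 else np.inf
        while n_keep < len(pairs) and pairs[n_keep][0] == cut:
            n_keep += 1  # ties at the boundary are all retained
    G = nx.Graph()
    G.add_nodes_from(regions)
    for absr, rv, u, v in pairs[:n_keep]:
        G.add_edge(u, v, weight=1.0, r=float(rv), sign=int(np.sign(rv)))
    realized = n_keep / len(pairs)
    if realized > threshold_frac + 1e-12:
        logger.info(
            "threshold ties: realized fraction %.4f > requested %.4f",
            realized, threshold_frac,
        )
    n_mat = (
        n_matrix
        if n_matrix is not None
        else pd.DataFrame(np.nan, index=regions, columns=regions)
    )
    return CoactivationNetwork(
        r_matrix, n_mat, threshold_frac, G, condition, realized
    )


def scale_free_index(network_or_degrees, n_bins: int = 10):
    """Signed goodness of fit of the log-log degree distribution.

    Degrees (or weighted connectivities) are split into up to *n_bins*
    equal-occupancy bins; log10 of the per-bin frequency is regressed on
    log10 of the per-bin mean degree, and the index is R^2 * sign(-slope), so
    a decaying (scale-free-like) distribution scores positive.  Returns
    (index, reason): index is None with a reason when fewer than 3 distinct
    bins exist.
    """
    if isinstance(network_or_degrees, CoactivationNetwork):
        k = np.array([d for _, d in network_or_degrees.graph.degree()], float)
    else:
        k = np.asarray(network_or_degrees, dtype=float)
    k = k[k > 0]
    if len(k) < 3:
        return None, "fewer than 3 connected nodes"
    order = np.sort(k)
    total = len(order)
    # equal-occupancy bins over distinct degree values, then per-bin density
    # p(k) = freq / bin width (raw frequency is flat by construction)
    uniq, counts = np.unique(order, return_counts=True)
    if len(uniq) < 3:
        return None, "fewer than 3 occupied degree bins"
    n_eff = min(n_bins, len(uniq))
    groups = np.array_split(np.arange(len(uniq)), n_eff)
    xs, ys = [], []
    for g in groups:
        if len(g) == 0:
            continue
        kv, cv = uniq[g], counts[g]
        kbar = float((kv * cv).sum() / cv.sum())
        xs.append(kbar)
        ys.append(cv.sum())
    # widths from midpoints between adjacent bin edges
    edges = [xs[0] - (xs[1] - xs[0]) / 2]
    for a, b in zip(xs[:-1], xs[1:]):
        edges.append((a + b) / 2)
    edges.append(xs[-1] + (xs[-1] - xs[-2]) / 2)
    widths = np.diff(edges)
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float) / total / np.maximum(widths, 1e-12)
    if len(xs) < 3:
        return None, "fewer than 3 occupied degree bins"
    lx, ly = np.log10(xs), np.log10(ys)
    slope, intercept = np.polyfit(lx, ly, 1)
    fitted = slope * lx + intercept
    ss_res = float(((ly - fitted) ** 2).sum())
    ss_tot = float(((ly - ly.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return r2 * (1.0 if slope < 0 else -1.0), None


def pct_connectivity(network: CoactivationNetwork) -> float:
    """Percent of regions with at least one retained edge."""
    G = network.graph
    n = G.number_of_nodes()
    if n == 0:
        return 0.0
    return 100.0 * sum(1 for _, d in G.degree() if d >= 1) / n


def graph_density(G: nx.Graph) -> float:
    n = G.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * G.number_of_edges() / (n * (n - 1))


def small_worldness(
    network_or_graph, n_random: int = 100, seed: int = 0
) -> tuple[float, float]:
    """Small-worldness sigma = (C/C_rand) / (L/L_rand), plus network density.

    C and L are the mean clustering coefficient and characteristic path
    length of the largest connected component; the random reference averages
    *n_random* Erdos-Renyi G(n, m) graphs with matched node and edge counts
    (largest-component convention when disconnected).
    """
    G = (
        network_or_graph.graph
        if isinstance(network_or_graph, CoactivationNetwork)
        else network_or_graph
    )
    comps = sorted(nx.connected_components(G), key=len, reverse=True)
    if not comps or len(comps[0]) < 4:
        raise ValueError("largest connected component has < 4 nodes")
    H = G.subgraph(comps[0])
    C = nx.average_clustering(H)
    L = nx.average_shortest_path_length(H)
    rng = np.random.default_rng(seed)
    n, m = G.number_of_nodes(), G.number_of_edges()
    Cr, Lr, used = 0.0, 0.0, 0
    n_disconnected = 0
    for _ in range(n_random):
        R = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31 - 1)))
        rc = max(nx.connected_components(R), key=len)
        if len(rc) < 2:
            continue
        if len(rc) < n:
            n_disconnected += 1
        Rh = R.subgraph(rc)
        Cr += nx.average_clustering(Rh)
        Lr += nx.average_shortest_path_length(Rh)
        used += 1
    if n_disconnected:
        logger.info(
            "small-worldness: %d/%d random graphs disconnected; "
            "largest-component convention used", n_disconnected, n_random,
        )
    if used == 0 or Cr == 0:
        raise ValueError("random reference degenerate")
    Cr /= used
    Lr /= used
    sigma = (C / Cr) / (L / Lr)
    return float(sigma), graph_density(G)


def sweep_thresholds(
    r_matrix: pd.DataFrame,
    fracs=(0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.40, 0.50),
    n_random: int = 50,
    seed: int = 0,
    connectivity_floor: float = 50.0,
) -> ThresholdSweep:
    """Network metrics across threshold fractions, with a recommended cutoff.

    The recommendation is the smallest fraction whose scale-free index is
    defined and positive while percent connectivity stays at or above
    *connectivity_floor*.
    """
    rows = []
    recommended = None
    for frac in sorted(set(fracs)):
        net = threshold_network(r_matrix, frac)
        sfi, reason = scale_free_index(net)
        pc = pct_connectivity(net)
        try:
            sigma, dens = small_worldness(net, n_random=n_random, seed=seed)
        except ValueError:
            sigma, dens = np.nan, graph_density(net.graph)
        rows.append(
            {
                "threshold_frac": frac,
                "scale_free_index": np.nan if sfi is None else sfi,
                "sfi_undefined_reason": reason or "",
                "pct_connectivity": pc,
                "small_worldness": sigma,
                "density": dens,
            }
        )
        if (
            recommended is None
            and sfi is not None
            and sfi > 0
            and pc >= connectivity_floor
        ):
            recommended = frac
    return ThresholdSweep(pd.DataFrame(rows), recommended)


def centrality(network: CoactivationNetwork) -> pd.DataFrame:
    """Degree and unnormalized betweenness per region, with dense ranks
    (rank 1 = highest)."""
    G = network.graph
    deg = dict(G.degree())
    btw = nx.betweenness_centrality(G, normalized=False)
    df = pd.DataFrame(
        {
            "degree": pd.Series(deg),
            "betweenness": pd.Series(btw),
        }
    )
    df["degree_rank"] = df["degree"].rank(ascending=False, method="min").astype(int)
    df["betweenness_rank"] = (
        df["betweenness"].rank(ascending=False, method="min").astype(int)
    )
    return df.loc[list(network.r_matrix.index)]


def identify_hubs(table: pd.DataFrame, top_frac: float = 0.20) -> list[str]:
    """Hubs = intersection of top-20% regions by degree and by betweenness.

    Ties at the rank boundary are included (and logged).
    """
    n = len(table)
    if n < 5:
        raise ValueError("need >= 5 regions")
    k = math.ceil(top_frac * n)

    def top_set(col: str) -> set:
        ranked = table[col].rank(ascending=False, method="min")
        cutoff_rank = sorted(ranked)[k - 1]
        chosen = set(table.index[ranked <= cutoff_rank])
        if len(chosen) > k:
            logger.info(
                "hub boundary tie on %s: %d regions at top-%d", col, len(chosen), k
            )
        return chosen

    hubs = top_set("degree") & top_set("betweenness")
    return sorted(hubs)


def louvain_communities(
    network_or_graph, seed: int = 0
) -> dict[str, int]:
    """Seeded Louvain modularity partition; isolated graphs fall back to one
    singleton community per node."""
    G = (
        network_or_graph.graph
        if isinstance(network_or_graph, CoactivationNetwork)
        else network_or_graph
    )
    if G.number_of_edges() == 0:
        return {node: i for i, node in enumerate(G.nodes)}
    parts = nx.community.louvain_communities(G, seed=seed)
    out = {}
    for cid, nodes in enumerate(sorted(parts, key=lambda s: -len(s))):
        for node in nodes:
            out[node] = cid
    return out


def export_edge_list(network: CoactivationNetwork, path) -> None:
    rows = [
        {"source": u, "target": v, "r": d["r"], "sign": d["sign"]}
        for u, v, d in network.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "r", "sign"]).to_csv(
        path, sep="\t", index=False
    )
    logger.info("wrote %d edges to %s", len(rows), path)


def export_graphml(network: CoactivationNetwork, path) -> None:
    nx.write_graphml(network.graph, path)
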