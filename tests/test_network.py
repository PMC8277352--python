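"""Co-activation network construction, threshold selection, centrality, hubs
and communities."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from fosmap import network as net
from fosmap.synth import SyntheticSpec, make_activity

from conftest import make_dataset


def modular_r_matrix(seed: int, n_regions: int = 30, loading: float = 0.8):
    spec = SyntheticSpec(
        seed=seed, n_regions=n_regions, n_modules=3, module_loading=loading,
        n_per_condition={"baseline": 12},
    )
    ds, truth = make_activity(spec)
    r, n = net.correlation_matrix(ds)
    return r, n, truth


def brute_force_betweenness(G: nx.Graph) -> dict:
    """All-pairs shortest-path enumeration oracle (independent of networkx
    centrality): for each unordered pair, enumerate ALL shortest paths by BFS
    back-tracing and split the pair's unit weight equally among them."""
    nodes = list(G.nodes)
    btw = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(G, s, t))
        except nx.NetworkXNoPath:
            continue
        w = 1.0 / len(paths)
        for path in paths:
            for v in path[1:-1]:
                btw[v] += w
    return btw


class TestCorrelationMatrix:
    def test_duplicated_region_perfectly_correlated(self):
        rng = np.random.default_rng(0)
        col = rng.uniform(1, 50, 8)
        ds = make_dataset({"baseline": np.column_stack([col, col, rng.uniform(1, 50, 8)])})
        r, n = net.correlation_matrix(ds)
        assert r.loc["R0", "R1"] == pytest.approx(1.0)
        assert (n == 8).all().all()

    def test_pairwise_n_with_missing(self):
        ds = make_dataset({"baseline": [[1.0, 2.0], [3.0, np.nan], [5.0, 6.0],
                                        [7.0, 8.0]]})
        _, n = net.correlation_matrix(ds)
        assert n.loc["R0", "R1"] == 3
        assert n.loc["R0", "R0"] == 4

    def test_small_pairwise_n_invalidates_cell(self):
        ds = make_dataset({"baseline": [[1.0, 2.0], [3.0, np.nan],
                                        [5.0, np.nan], [7.0, 8.0]]})
        r, _ = net.correlation_matrix(ds)
        assert np.isnan(r.loc["R0", "R1"])

    def test_small_sample_noise_bounded(self):
        spec = SyntheticSpec(seed=1, n_regions=20, module_loading=0.0,
                             n_per_condition={"baseline": 8})
        ds, _ = make_activity(spec)
        r, _ = net.correlation_matrix(ds)
        off = r.to_numpy()[np.triu_indices(20, k=1)]
        assert np.abs(off).mean() < 0.45

    def test_within_module_exceeds_between(self):
        hits = 0
        for seed in range(20):
            r, _, truth = modular_r_matrix(seed)
            mods = truth["module_assignments"]
            within, between = [], []
            for a, b in itertools.combinations(r.index, 2):
                (within if mods[a] == mods[b] else between).append(r.loc[a, b])
            hits += np.mean(within) > np.mean(between)
        assert hits >= 19  # >= 95% of seeds


class TestThresholdNetwork:
    def test_full_fraction_gives_complete_graph(self):
        r, _, _ = modular_r_matrix(0, n_regions=10)
        network = net.threshold_network(r, 1.0)
        assert network.graph.number_of_edges() == 45

    def test_single_dominant_edge_retained(self):
        regions = ["A", "B", "C", "D"]
        m = np.eye(4) * 0.0 + 0.1
        m[0, 1] = m[1, 0] = 0.95
        np.fill_diagonal(m, 1.0)
        r = pd.DataFrame(m, index=regions, columns=regions)
        network = net.threshold_network(r, 1 / 6)
        assert set(map(frozenset, network.graph.edges)) == {frozenset({"A", "B"})}

    def test_negative_correlations_rank_by_magnitude(self):
        regions = ["A", "B", "C"]
        m = np.array([[1.0, -0.9, 0.2], [-0.9, 1.0, 0.1], [0.2, 0.1, 1.0]])
        r = pd.DataFrame(m, index=regions, columns=regions)
        network = net.threshold_network(r, 1 / 3)
        assert network.graph.has_edge("A", "B")
        assert network.graph["A"]["B"]["sign"] == -1

    def test_ties_at_cutoff_all_retained(self):
        regions = ["A", "B", "C", "D"]
        m = np.full((4, 4), 0.5)
        np.fill_diagonal(m, 1.0)
        r = pd.DataFrame(m, index=regions, columns=regions)
        network = net.threshold_network(r, 1 / 6)
        assert network.graph.number_of_edges() == 6
        assert network.realized_frac == 1.0

    def test_invalid_fraction_rejected(self):
        r, _, _ = modular_r_matrix(0, n_regions=5)
        with pytest.raises(ValueError):
            net.threshold_network(r, 0.0)

    def test_degree_sum_is_twice_edges(self):
        for frac in (0.05, 0.1, 0.3):
            r, _, _ = modular_r_matrix(2)
            network = net.threshold_network(r, frac)
            degs = [d for _, d in network.graph.degree()]
            assert sum(degs) == 2 * network.graph.number_of_edges()


class TestScaleFreeIndex:
    def test_regular_graph_undefined(self):
        G = nx.cycle_graph(20)
        sfi, reason = net.scale_free_index([d for _, d in G.degree()])
        assert sfi is None
        assert "bins" in reason or "nodes" in reason

    def test_preferential_attachment_scores_high(self):
        hits = 0
        for seed in range(20):
            G = nx.barabasi_albert_graph(200, 3, seed=seed)
            sfi, _ = net.scale_free_index([d for _, d in G.degree()])
            hits += sfi is not None and sfi > 0.5
        assert hits >= 18

    def test_dense_random_graph_scores_low(self):
        """A binomial degree distribution is not scale-free: its index
        magnitude stays small and far below the preferential-attachment
        index (its sign is sampling noise around the flat log-log slope)."""
        for seed in range(10):
            G = nx.gnp_random_graph(200, 0.5, seed=seed)
            sfi, _ = net.scale_free_index([d for _, d in G.degree()])
            assert sfi is not None and abs(sfi) < 0.5


class TestConnectivityAndDensity:
    def test_pct_connectivity_cases(self):
        r, _, _ = modular_r_matrix(0, n_regions=10)
        assert net.pct_connectivity(net.threshold_network(r, 1.0)) == 100.0
        # star over 5 of 10 nodes
        G = nx.Graph()
        G.add_nodes_from(range(10))
        G.add_edges_from((0, i) for i in range(1, 5))
        network = net.CoactivationNetwork(
            pd.DataFrame(np.eye(10)), pd.DataFrame(), 0.1, G
        )
        assert net.pct_connectivity(network) == 50.0

    def test_density_closed_form(self):
        G = nx.path_graph(10)  # N=10, E=9
        assert net.graph_density(G) == pytest.approx(0.2)


class TestSmallWorldness:
    def test_complete_graph_sigma_one(self):
        G = nx.complete_graph(10)
        sigma, density = net.small_worldness(G, n_random=20, seed=0)
        assert density == 1.0
        assert sigma == pytest.approx(1.0, abs=1e-9)

    def test_rewiring_a_lattice_raises_sigma(self):
        """Watts-Strogatz property: rewiring shortcuts increase sigma."""
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            sigmas = []
            for p in (0.0, 0.05, 0.10):
                G = nx.watts_strogatz_graph(50, 4, p, seed=seed)
                sigma, _ = net.small_worldness(G, n_random=20, seed=seed)
                sigmas.append(sigma)
            hits += sigmas[2] > sigmas[0]
        assert hits >= 0.8 * n_seeds


class TestSweepThresholds:
    def test_single_fraction_single_row(self):
        r, _, _ = modular_r_matrix(1)
        sweep = net.sweep_thresholds(r, fracs=[0.1], n_random=5, seed=0)
        assert len(sweep.table) == 1

    def test_unsorted_input_sorted_output(self):
        r, _, _ = modular_r_matrix(1)
        sweep = net.sweep_thresholds(r, fracs=[0.3, 0.05, 0.1], n_random=5,
                                     seed=0)
        assert list(sweep.table["threshold_frac"]) == [0.05, 0.1, 0.3]

    def test_modular_matrix_recommends_sparse_cutoff(self):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            r, _, _ = modular_r_matrix(seed)
            sweep = net.sweep_thresholds(
                r, fracs=(0.05, 0.10, 0.15, 0.20, 0.25), n_random=10, seed=seed
            )
            hits += sweep.recommended is not None and sweep.recommended <= 0.2
        assert hits >= 0.8 * n_seeds


class TestCentrality:
    def test_star_and_complete_closed_forms(self):
        star = nx.star_graph(4)  # center 0, 4 leaves
        network = net.CoactivationNetwork(
            pd.DataFrame(np.eye(5)), pd.DataFrame(), 0.1, star
        )
        table = net.centrality(network)
        assert table.loc[0, "betweenness"] == pytest.approx(6.0)
        assert (table.loc[1:, "betweenness"] == 0).all()
        comp = nx.complete_graph(6)
        network = net.CoactivationNetwork(
            pd.DataFrame(np.eye(6)), pd.DataFrame(), 0.1, comp
        )
        assert (net.centrality(network)["betweenness"] == 0).all()

    def test_matches_brute_force_oracle_on_small_graphs(self):
        rng = np.random.default_rng(0)
        for trial in range(15):
            n = int(rng.integers(5, 11))
            G = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(2**31)))
            network = net.CoactivationNetwork(
                pd.DataFrame(np.eye(n)), pd.DataFrame(), 0.1, G
            )
            ours = net.centrality(network)["betweenness"]
            oracle = brute_force_betweenness(G)
            for node, val in oracle.items():
                assert ours[node] == pytest.approx(val, abs=1e-9)

    def test_matches_oracle_on_atlas_graphs(self):
        """Exhaustive check over every connected graph with <= 6 nodes."""
        from networkx.generators.atlas import graph_atlas_g

        checked = 0
        for G in graph_atlas_g():
            if G.number_of_nodes() > 6 or G.number_of_nodes() < 3:
                continue
            if not nx.is_connected(G):
                continue
            ours = nx.betweenness_centrality(G, normalized=False)
            oracle = brute_force_betweenness(G)
            for node in G.nodes:
                assert ours[node] == pytest.approx(oracle[node], abs=1e-9)
            checked += 1
        assert checked > 100


class TestIdentifyHubs:
    def _table(self, degree, betweenness):
        return pd.DataFrame({"degree": degree, "betweenness": betweenness})

    def test_dominant_node_is_hub(self):
        deg = [1] * 19 + [10]
        btw = [0.0] * 19 + [50.0]
        hubs = net.identify_hubs(self._table(deg, btw))
        assert 19 in [int(h) for h in hubs]

    def test_disjoint_rankings_give_empty_set(self):
        deg = list(range(20))
        btw = list(range(19, -1, -1))
        assert net.identify_hubs(self._table(deg, btw)) == []

    def test_too_few_regions_rejected(self):
        with pytest.raises(ValueError):
            net.identify_hubs(self._table([1, 2], [3, 4]))

    def test_planted_connector_found(self):
        """Hub-and-spoke module network: the connector joins two cliques."""
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            G = nx.Graph()
            c1 = [f"a{i}" for i in range(8)]
            c2 = [f"b{i}" for i in range(8)]
            for group in (c1, c2):
                for u, v in itertools.combinations(group, 2):
                    if rng.random() < 0.8:
                        G.add_edge(u, v)
            G.add_edge("hub", c1[0])
            for node in c1 + c2:
                if rng.random() < 0.5:
                    G.add_edge("hub", node)
            regions = c1 + c2 + ["hub"]
            network = net.CoactivationNetwork(
                pd.DataFrame(np.eye(len(regions)), index=regions,
                             columns=regions),
                pd.DataFrame(), 0.1, G,
            )
            hubs = net.identify_hubs(net.centrality(network))
            hits += "hub" in hubs
        assert hits >= 0.9 * n_seeds


class TestLouvain:
    def test_two_cliques_two_communities(self):
        G = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        comm = net.louvain_communities(G, seed=0)
        assert len(set(comm.values())) == 2
        assert len({comm[i] for i in range(5)}) == 1
        assert len({comm[i] for i in range(5, 10)}) == 1

    def test_same_seed_identical_partition(self):
        r, _, _ = modular_r_matrix(3)
        network = net.threshold_network(r, 0.15)
        assert net.louvain_communities(network, seed=5) == \
            net.louvain_communities(network, seed=5)

    def test_empty_graph_singletons(self):
        G = nx.empty_graph(4)
        comm = net.louvain_communities(G, seed=0)
        assert sorted(comm.values()) == [0, 1, 2, 3]

    def test_planted_modules_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            r, _, truth = modular_r_matrix(seed)
            # with 3 modules of 10, within-module pairs are ~31% of all
            # pairs, so the threshold must retain a comparable fraction
            network = net.threshold_network(r, 0.20)
            comm = net.louvain_communities(network, seed=seed)
            mods = truth["module_assignments"]
            regions = list(r.index)
            ari = adjusted_rand_score(
                [mods[x] for x in regions], [comm[x] for x in regions]
            )
            hits += ari > 0.8
        assert hits >= 0.9 * n_seeds


class TestExports:
    def test_edge_list_round_trip(self, tmp_path):
        r, n, _ = modular_r_matrix(0, n_regions=10)
        network = net.threshold_network(r, 0.2, n)
        path = tmp_path / "edges.tsv"
        net.export_edge_list(network, path)
        table = pd.read_csv(path, sep="\t")
        assert len(table) == network.graph.number_of_edges()
        assert set(table.columns) == {"source", "target", "r", "sign"}

    def test_graphml_written(self, tmp_path):
        r, _, _ = modular_r_matrix(0, n_regions=8)
        network = net.threshold_network(r, 0.3)
        path = tmp_path / "net.graphml"
        net.export_graphml(network, path)
        back = nx.read_graphml(path)
        assert back.number_of_edges() == network.graph.number_of_edges()
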