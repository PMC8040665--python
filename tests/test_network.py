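"""Signaling-network construction, metrics, roles, communities, robustness."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from inflamsig import simulate as sim
from inflamsig._rng import derive_rng
from inflamsig.network import (
    SignalingNetwork,
    build_network,
    category_enrichment,
    classify_roles,
    detect_communities,
    node_centralities,
    node_median_correlations,
    robustness_test,
    spearman_matrix,
    topology_over_time,
)

from conftest import single_cohort_config


# ------------------------------------------------------------------ #
# Independent brute-force oracles (pure python BFS / path enumeration)


def bfs_distances(adj, s):
    dist = {s: 0}
    frontier = [s]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def brute_betweenness(adj, nodes):
    """Count shortest paths through each node by explicit enumeration."""

    def all_shortest_paths(s, t, dist):
        if t not in dist:
            return []
        paths = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(path)
                return
            for v in adj[u]:
                if v in dist and dist[v] == dist[u] + 1 and dist_t.get(v) is not None:
                    if dist[v] + dist_t[v] == dist[t]:
                        extend(path + [v])

        dist_t = bfs_distances(adj, t)
        extend([s])
        return paths

    bc = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        dist = bfs_distances(adj, s)
        paths = all_shortest_paths(s, t, dist)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / len(paths)
    return bc


def brute_eccentricity(adj, nodes):
    ecc = {}
    for v in nodes:
        dist = bfs_distances(adj, v)
        ecc[v] = max(dist.values()) if len(dist) > 1 else 0
    return ecc


def _net_from_graph(g: nx.Graph) -> SignalingNetwork:
    corr = pd.DataFrame(
        np.eye(len(g)), index=list(g.nodes), columns=list(g.nodes)
    )
    for u, v in g.edges:
        corr.loc[u, v] = corr.loc[v, u] = 0.9
    return build_network(corr, threshold=0.5)


class TestSpearman:
    def test_monotone_transform_gives_unit_correlation(self):
        x = np.arange(1.0, 11)
        df = pd.DataFrame({"a": x, "b": x**3})
        rho = spearman_matrix(df)
        assert rho.loc["a", "b"] == pytest.approx(1.0)
        assert (np.diag(rho) == 1).all()

    def test_hand_ranked_ties_oracle(self):
        # x has a tie at value 2 -> average ranks (1, 2.5, 2.5, 4, 5)
        df = pd.DataFrame(
            {"x": [1.0, 2, 2, 3, 4], "y": [5.0, 4, 3, 2, 1]}
        )
        rx = np.array([1, 2.5, 2.5, 4, 5])
        ry = np.array([5, 4, 3, 2, 1])
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman_matrix(df).loc["x", "y"] == pytest.approx(
            expected, abs=1e-12
        )

    def test_constant_feature_isolated(self):
        df = pd.DataFrame(
            {"a": [1.0, 2, 3, 4], "b": [2.0, 2, 2, 2], "c": [4.0, 3, 2, 1]}
        )
        rho = spearman_matrix(df)
        assert np.isnan(rho.loc["a", "b"])
        assert rho.loc["b", "b"] == 1.0
        net = build_network(rho, 0.5)
        assert net.graph.degree("b") == 0

    def test_minimum_subjects(self):
        with pytest.raises(ValueError, match=">= 4"):
            spearman_matrix(pd.DataFrame({"a": [1, 2], "b": [2, 1]}))


class TestBuildNetwork:
    def test_84_nodes_from_default_panel(self, subjects, small_panel):
        ds = sim.simulate_measurements(
            subjects, small_panel,
            community_spec=sim.default_community_spec(small_panel), seed=0,
        )
        hcv = ds.subset_samples((ds.subjects.cohort == "hcv").to_numpy())
        net = build_network(spearman_matrix(hcv.measurements), 0.5)
        assert net.graph.number_of_nodes() == 84

    def test_identity_matrix_has_no_edges(self):
        corr = pd.DataFrame(np.eye(10))
        net = build_network(corr, 0.5)
        assert net.graph.number_of_edges() == 0
        assert all(d == 0 for _, d in net.graph.degree)

    def test_null_features_give_sparse_network(self):
        edges = []
        for s in range(5):
            rng = derive_rng(s, "nulledges")
            X = pd.DataFrame(rng.normal(size=(100, 84)))
            edges.append(
                build_network(spearman_matrix(X), 0.5).graph.number_of_edges()
            )
        assert max(edges) < 5

    def test_threshold_validation(self):
        with pytest.raises(ValueError, match="threshold"):
            build_network(pd.DataFrame(np.eye(3)), threshold=0.0)

    def test_threshold_monotonicity(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 20)))
        corr = spearman_matrix(X)
        e_lo = set(map(frozenset, build_network(corr, 0.3).graph.edges))
        e_hi = set(map(frozenset, build_network(corr, 0.5).graph.edges))
        assert e_hi <= e_lo

    def test_strength_is_sum_of_abs_rho(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 6)))
        corr = spearman_matrix(X)
        net = build_network(corr, 0.2)
        for v in net.graph.nodes:
            expect = sum(
                abs(d["rho"]) for _, _, d in net.graph.edges(v, data=True)
            )
            assert net.graph.nodes[v]["strength"] == pytest.approx(expect)


class TestCentralities:
    def test_path_graph(self):
        g = nx.path_graph(["a", "b", "c", "d", "e"])
        net = _net_from_graph(g)
        tbl = node_centralities(net).set_index("node")
        assert tbl.loc["c", "betweenness"] == pytest.approx(4.0)
        assert tbl.loc["c", "eccentricity"] == 2
        assert tbl.loc["a", "eccentricity"] == 4

    def test_star_graph(self):
        g = nx.star_graph(7)  # center 0, leaves 1..7
        tbl = node_centralities(_net_from_graph(g)).set_index("node")
        assert tbl.loc[0, "betweenness"] == pytest.approx(21.0)  # C(7,2)
        assert (tbl.drop(index=0).betweenness == 0).all()

    def test_complete_graph(self):
        tbl = node_centralities(_net_from_graph(nx.complete_graph(6)))
        assert (tbl.betweenness == 0).all()
        assert (tbl.eccentricity == 1).all()

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(99)
        for trial in range(200):
            n = int(rng.integers(2, 9))
            p = float(rng.uniform(0.15, 0.9))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
            net = _net_from_graph(g)
            tbl = node_centralities(net).set_index("node")
            adj = {v: set(g.neighbors(v)) for v in g.nodes}
            bc = brute_betweenness(adj, list(g.nodes))
            ecc = brute_eccentricity(adj, list(g.nodes))
            for v in g.nodes:
                assert tbl.loc[v, "betweenness"] == pytest.approx(
                    bc[v], abs=1e-9
                ), f"betweenness mismatch at trial {trial}"
                assert tbl.loc[v, "eccentricity"] == ecc[v]


class TestRoles:
    def _net_with_degrees(self, n, distinct=True):
        g = nx.Graph()
        g.add_nodes_from(range(n))
        # chain of increasing degree via preferential attachment style
        for i in range(1, n):
            for j in range(min(i, (i % 5) + 1)):
                g.add_edge(i, j)
        return _net_from_graph(g)

    def test_84_nodes_yield_17_hubs(self, subjects, small_panel):
        ds = sim.simulate_measurements(
            subjects, small_panel,
            community_spec=sim.default_community_spec(small_panel), seed=1,
        )
        aging = ds.subset_samples((ds.subjects.cohort == "aging").to_numpy())
        net = build_network(spearman_matrix(aging.measurements), 0.5)
        node_centralities(net)
        roles = classify_roles(net)
        hubs = roles[roles.role.str.startswith("H")]
        # ceil(0.2 * 84) = 17 plus any boundary ties
        assert len(hubs) >= 17

    def test_ten_distinct_degrees_two_hubs(self):
        g = nx.Graph()
        for i in range(10):
            for j in range(i):
                g.add_edge(f"n{i}", f"n{j}")
        # complete graph has equal degrees; remove edges to make distinct
        g = nx.path_graph([f"p{i}" for i in range(10)])
        for i in range(2, 10):
            g.add_edge("p0", f"p{i}")  # p0 highest degree
        net = _net_from_graph(g)
        node_centralities(net)
        roles = classify_roles(net).set_index("node")
        degrees = dict(net.graph.degree)
        ranked = sorted(degrees.values(), reverse=True)
        cutoff = ranked[1]  # ceil(0.2*10) = 2
        hubs = {v for v, d in degrees.items() if d >= cutoff}
        got = set(roles[roles.role.str.startswith("H-")].index)
        assert got == hubs

    def test_hub_and_bottleneck_is_HB(self):
        g = nx.barbell_graph(5, 1)  # bridge node is both high-betweenness
        net = _net_from_graph(g)
        node_centralities(net)
        roles = classify_roles(net).set_index("node")
        bridge = 5  # connector in barbell(5,1)
        assert roles.loc[bridge, "role"] in {"H-B", "NH-B"}
        assert (roles.role.isin(["H-B", "H-NB", "NH-B", "NH-NB"])).all()

    def test_all_equal_metric_classifies_none(self):
        net = _net_from_graph(nx.complete_graph(8))
        node_centralities(net)
        roles = classify_roles(net)
        assert (roles.role == "NH-NB").all()

    def test_empty_network_rejected(self):
        net = SignalingNetwork(nx.Graph(), 0.5)
        with pytest.raises(ValueError, match="empty"):
            classify_roles(net)


class TestCommunities:
    def test_two_cliques_q_half(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        net = _net_from_graph(g)
        table = detect_communities(net, seed=0)
        assert table.community.nunique() == 2
        assert table.attrs["modularity_q"] == pytest.approx(0.5, abs=1e-12)

    def test_single_clique_q_zero(self):
        net = _net_from_graph(nx.complete_graph(6))
        table = detect_communities(net, seed=0)
        assert table.community.nunique() == 1
        assert table.attrs["modularity_q"] == pytest.approx(0.0, abs=1e-12)

    def test_edgeless_network_singletons(self):
        corr = pd.DataFrame(np.eye(5))
        net = build_network(corr, 0.5)
        table = detect_communities(net, seed=0)
        assert table.community.nunique() == 5
        assert table.attrs["modularity_q"] == 0.0

    def test_composition_percentages(self):
        g = nx.disjoint_union(nx.complete_graph(40), nx.complete_graph(44))
        net = _net_from_graph(g)
        table = detect_communities(net, seed=0)
        comp = table.attrs["composition"]
        assert comp.composition_pct.sum() == pytest.approx(100.0)
        assert comp.composition_pct.round(1).isin([47.6, 52.4]).all()

    def test_planted_blocks_recovered(self, small_panel):
        from sklearn.metrics import adjusted_rand_score

        aris = []
        for s in range(5):
            subj = sim.generate_subjects(single_cohort_config(100), seed=s)
            ds = sim.simulate_measurements(
                subj, small_panel,
                community_spec=sim.default_community_spec(small_panel),
                seed=s,
            )
            corr = spearman_matrix(ds.measurements)
            net = build_network(corr, 0.5)
            table = detect_communities(net, seed=s)
            truth = small_panel.set_index("feature_id").loc[
                table.node, "pathway"
            ]
            aris.append(adjusted_rand_score(truth, table.community))
        assert np.median(aris) >= 0.9


class TestEnrichment:
    def test_whole_universe_p_one(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 8)))
        net = build_network(spearman_matrix(X), 0.2)
        cats = {c: ("even" if i % 2 == 0 else "odd") for i, c in enumerate(X.columns)}
        table = category_enrichment(net, cats, set(X.columns))
        assert (table.p == 1.0).all()

    def test_hub_param_concentration_matches_combinatorics(self):
        from math import comb

        corr = pd.DataFrame(np.eye(84), index=range(84), columns=range(84))
        net = build_network(corr, 0.5)
        cats = {v: ("pp38" if v < 7 else "other") for v in range(84)}
        subset = set(range(7)) | set(range(40, 50))  # 17 nodes, all 7 pp38
        table = category_enrichment(net, cats, subset).set_index("category")
        expected = comb(77, 10) / comb(84, 17)
        assert table.loc["pp38", "p"] == pytest.approx(expected, rel=1e-12)

    def test_empty_subset_rejected(self):
        corr = pd.DataFrame(np.eye(4))
        net = build_network(corr, 0.5)
        with pytest.raises(ValueError, match="empty"):
            category_enrichment(net, {i: "x" for i in range(4)}, set())


class TestRobustness:
    def _random_corr(self, seed, n_nodes=30, n_subj=50):
        rng = derive_rng(seed, "robcorr")
        X = pd.DataFrame(
            rng.normal(size=(n_subj, n_nodes)),
            columns=[f"v{i}" for i in range(n_nodes)],
        )
        return spearman_matrix(X)

    def test_identical_timepoints_p_one(self):
        C = self._random_corr(0)
        rep = robustness_test({"t1": C, "t2": C}, n_perm=500, seed=0)
        assert (rep.frame.delta_obs == 0).all()
        assert (rep.frame.p == 1.0).all()

    def test_p_granularity(self):
        C1, C2 = self._random_corr(1), self._random_corr(2)
        rep = robustness_test({"a": C1, "b": C2}, n_perm=10, seed=3)
        steps = (rep.frame.p * 10).round(9)
        assert np.allclose(steps, steps.round())

    def test_planted_rewired_node_detected(self):
        pvals = []
        for s in range(11):
            C1 = self._random_corr(100 + s, n_nodes=84)
            C2 = C1.copy()
            node = C2.index[0]
            shifted = (C2.loc[node] + 0.6).clip(upper=1.0)
            C2.loc[node] = shifted
            C2.loc[:, node] = shifted
            np.fill_diagonal(C2.values, 1.0)
            rep = robustness_test({"t1": C1, "t2": C2}, n_perm=10000, seed=s)
            pvals.append(
                rep.frame[rep.frame.node == node].p.iloc[0]
            )
        assert np.median(pvals) < 0.01

    def test_mismatched_nodes_rejected(self):
        C1 = self._random_corr(5, n_nodes=6)
        C2 = self._random_corr(6, n_nodes=7)
        with pytest.raises(ValueError, match="node sets"):
            robustness_test({"a": C1, "b": C2}, n_perm=100, seed=0)

    def test_subject_null_mode(self):
        rng = derive_rng(9, "subjnull")
        X1 = pd.DataFrame(rng.normal(size=(30, 10)))
        X2 = pd.DataFrame(rng.normal(size=(30, 10)))
        C1, C2 = spearman_matrix(X1), spearman_matrix(X2)
        rep = robustness_test(
            {"a": C1, "b": C2},
            n_perm=50,
            seed=9,
            null="subjects",
            data_by_timepoint={"a": X1, "b": X2},
        )
        assert ((rep.frame.p >= 0) & (rep.frame.p <= 1)).all()

    def test_median_correlation_helper(self):
        corr = pd.DataFrame(
            [[1.0, 0.2, 0.8], [0.2, 1.0, 0.4], [0.8, 0.4, 1.0]],
            index=list("abc"),
            columns=list("abc"),
        )
        m = node_median_correlations(corr)
        assert m["a"] == pytest.approx(0.5)  # median of 0.2, 0.8


class TestTopologyOverTime:
    def test_identical_networks_p_one(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 15)))
        corr = spearman_matrix(X)
        n1 = build_network(corr, 0.3)
        n2 = build_network(corr, 0.3)
        summary, tests = topology_over_time({"pre": n1, "post": n2})
        assert (tests.p == 1.0).all()
        med = summary.pivot(index="metric", columns="timepoint", values="median")
        assert (med["pre"] == med["post"]).all()

    def test_planted_thinning_recovered(self, small_panel):
        # weaker block loading at mid-timepoint -> sparser network
        subj = sim.generate_subjects(single_cohort_config(80), seed=4)
        nets = {}
        for tp, load in (("pre", 0.85), ("mid", 0.4)):
            ds = sim.simulate_measurements(
                subj, small_panel,
                community_spec=sim.default_community_spec(small_panel, load),
                seed=4,
            )
            corr = spearman_matrix(ds.measurements)
            nets[tp] = build_network(corr, 0.5)
        summary, _ = topology_over_time(nets)
        med = summary.pivot(index="metric", columns="timepoint", values="median")
        assert med.loc["degree", "mid"] < med.loc["degree", "pre"]

    def test_graphml_round_trip(self, tmp_path, rng):
        X = pd.DataFrame(
            rng.normal(size=(30, 8)), columns=[f"f{i}" for i in range(8)]
        )
        net = build_network(spearman_matrix(X), 0.3)
        node_centralities(net)
        classify_roles(net)
        detect_communities(net, seed=0)
        path = tmp_path / "net.graphml"
        net.to_graphml(path)
        back = nx.read_graphml(path)
        assert set(back.nodes) == set(map(str, net.graph.nodes))
        v = list(net.graph.nodes)[0]
        assert back.nodes[str(v)]["degree"] == net.graph.nodes[v]["degree"]
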