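"""Core-network construction, graph statistics, random baselines, MCODE
modules, edge-betweenness communities, and hub/connector rules."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from planktonet.network import (
    classify_central,
    filter_core,
    girvan_newman_modularity,
    mcode_modules,
    network_stats,
    node_metrics,
    random_baseline,
    seasonal_subnetwork,
)


def assoc_row(a, b, ls=0.9, rho=0.9, q=1e-5, sign=1, ka="otu", kb="otu"):
    return {
        "node_a": a, "node_b": b, "kind_a": ka, "kind_b": kb,
        "ls": ls, "sign": sign, "spearman": rho, "q": q, "p": q,
    }


class TestFilterCore:
    def test_threshold_examples(self):
        table = pd.DataFrame([
            assoc_row("a", "b", ls=0.75, rho=0.80, q=1e-4),   # retained
            assoc_row("a", "c", ls=0.75, rho=0.65, q=1e-4),   # rho fails
            assoc_row("b", "c", ls=0.60, rho=0.90, q=1e-4),   # ls fails
            assoc_row("c", "d", ls=0.90, rho=0.90, q=0.01),   # q fails
        ])
        g = filter_core(table)
        assert set(g.edges) == {("a", "b")}
        assert set(g.nodes) == {"a", "b"}  # nodes without edges dropped

    def test_hand_filtered_count_on_random_scores(self):
        rng = np.random.default_rng(0)
        rows = []
        for i, (a, b) in enumerate(itertools.combinations(range(30), 2)):
            rows.append(
                assoc_row(
                    f"o{a}", f"o{b}",
                    ls=float(rng.uniform(-1, 1)),
                    rho=float(rng.uniform(-1, 1)),
                    q=float(rng.uniform(0, 0.01)),
                )
            )
        table = pd.DataFrame(rows)
        expected = (
            (table.ls.abs() > 0.7) & (table.spearman.abs() > 0.7) & (table.q < 0.001)
        ).sum()
        assert filter_core(table).number_of_edges() == expected

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(1)
        rows = [
            assoc_row(
                f"o{a}", f"o{b}",
                ls=float(rng.uniform(-1, 1)),
                rho=float(rng.uniform(-1, 1)),
                q=float(rng.uniform(0, 0.01)),
            )
            for a, b in itertools.combinations(range(20), 2)
        ]
        table = pd.DataFrame(rows)
        loose = filter_core(table, ls_min=0.5, rho_min=0.5, q_max=0.005)
        tight = filter_core(table, ls_min=0.8, rho_min=0.8, q_max=0.001)
        assert set(tight.edges) <= set(loose.edges)
        assert set(tight.nodes) <= set(loose.nodes)


class TestNetworkStats:
    def test_triangle(self):
        s = network_stats(nx.complete_graph(3))
        assert s.density == 1 and s.average_clustering == 1
        assert s.average_path_length == 1 and s.diameter == 1

    def test_path_on_three_nodes(self):
        s = network_stats(nx.path_graph(3))
        assert s.density == pytest.approx(2 / 3)
        assert s.average_path_length == pytest.approx(4 / 3)

    def test_table_sized_graph_density(self):
        g = random_baseline(262, 1411, "er", seed=0)
        s = network_stats(g, compute_modularity=False)
        assert round(s.density, 2) == 0.04
        assert s.average_degree == pytest.approx(2 * 1411 / 262)

    def test_er_density_is_exact_for_every_realization(self):
        for seed in range(5):
            g = random_baseline(40, 100, "er", seed=seed)
            s = network_stats(g, compute_modularity=False)
            assert s.density == pytest.approx(100 / (40 * 39 / 2))

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            network_stats(nx.Graph())


class TestNodeMetrics:
    def test_star_center(self):
        m = node_metrics(nx.star_graph(4))  # center 0 + 4 leaves
        assert m.loc[0, "betweenness"] == 1.0
        assert m.loc[0, "closeness"] == 1.0
        assert m.loc[1, "betweenness"] == 0.0

    def test_four_cycle(self):
        m = node_metrics(nx.cycle_graph(4))
        assert (m["degree"] == 2).all()
        assert (m["clustering"] == 0).all()

    def test_small_component_center_gets_unit_centralities(self):
        g = nx.union(nx.complete_graph(6), nx.path_graph(3), rename=("a", "b"))
        m = node_metrics(g)
        assert m.loc["b1", "betweenness"] == 1.0
        assert m.loc["b1", "closeness"] == 1.0


class TestRandomBaselines:
    def test_er_exact_edge_count(self):
        g = random_baseline(262, 1411, "er", seed=1)
        assert g.number_of_nodes() == 262 and g.number_of_edges() == 1411

    def test_er_average_path_length_matches_table(self):
        vals = []
        for seed in range(20):
            g = random_baseline(262, 1411, "er", seed=seed)
            giant = g.subgraph(max(nx.connected_components(g), key=len))
            vals.append(nx.average_shortest_path_length(giant))
        assert np.mean(vals) == pytest.approx(2.60, abs=0.05)

    def test_er_clustering_close_to_density(self):
        cs = [
            nx.average_clustering(random_baseline(262, 1411, "er", seed=s))
            for s in range(20)
        ]
        assert np.mean(cs) == pytest.approx(1411 / (262 * 261 / 2), abs=0.01)

    def test_ws_edge_count_matched(self):
        g = random_baseline(262, 1411, "ws", seed=2)
        assert g.number_of_edges() == 1411

    def test_ba_edge_count_closest_the_model_allows(self):
        g = random_baseline(262, 1411, "ba", seed=3)
        best = min(
            abs(m * (262 - m) - 1411) for m in range(1, 262)
        )
        assert abs(g.number_of_edges() - 1411) == best

    def test_infeasible_edge_count_rejected(self):
        with pytest.raises(ValueError):
            random_baseline(5, 11, "er")


class TestSeasonalSubnetworks:
    def _net(self):
        g = nx.Graph()
        for i in range(4):
            g.add_node(f"w{i}", kind="otu")
            g.add_node(f"s{i}", kind="otu")
        g.add_node("temp", kind="env")
        g.add_edges_from([("w0", "w1"), ("w1", "w2"), ("s0", "s1"), ("w0", "s0"), ("w0", "temp")])
        return g

    def test_induced_subgraph_counts(self):
        g = self._net()
        ann = {f"w{i}": "winter" for i in range(4)} | {f"s{i}": "summer" for i in range(4)}
        winter = seasonal_subnetwork(g, ann, "winter")
        assert set(winter.nodes) == {"w0", "w1", "w2", "w3"}
        assert winter.number_of_edges() == 2  # w0-w1, w1-w2 only
        assert "temp" not in winter

    def test_all_and_none(self):
        g = self._net()
        all_winter = {n: "winter" for n in g.nodes}
        assert seasonal_subnetwork(g, all_winter, "winter").number_of_nodes() == 8
        assert seasonal_subnetwork(g, all_winter, "summer").number_of_nodes() == 0

    def test_unknown_season_rejected(self):
        with pytest.raises(ValueError):
            seasonal_subnetwork(self._net(), {}, "monsoon")


class TestMcode:
    def test_isolated_five_clique_scores_five(self):
        mods = mcode_modules(nx.complete_graph(5))
        assert len(mods) == 1
        assert mods[0].score == pytest.approx(5.0)
        assert len(mods[0].nodes) == 5

    def test_bridged_cliques_merge_into_one_module(self):
        # every vertex weighs 4 (k-core 4, density 1), the bridge endpoint
        # passes the 0.8 x seed-weight admission, so greedy expansion
        # crosses the bridge: one module of 10, score 21/45 x 10
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        g.add_edge(0, 5)
        mods = mcode_modules(g)
        assert [len(m.nodes) for m in mods] == [10]
        assert mods[0].score == pytest.approx(21 / 45 * 10)

    def test_edgeless_graph_has_no_modules(self):
        g = nx.empty_graph(6)
        assert mcode_modules(g) == []

    def test_haircut_removes_pendants(self):
        g = nx.complete_graph(5)
        g.add_edge(0, 99)  # pendant
        mods = mcode_modules(g)
        assert len(mods[0].nodes) == 5 and "99" not in mods[0].nodes

    def test_invariant_to_relabeling(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(6, 14))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(2**31)))
            perm = rng.permutation(n)
            h = nx.relabel_nodes(g, {i: f"x{perm[i]}" for i in range(n)})
            sizes_g = sorted(len(m.nodes) for m in mcode_modules(g))
            sizes_h = sorted(len(m.nodes) for m in mcode_modules(h))
            scores_g = sorted(round(m.score, 9) for m in mcode_modules(g))
            scores_h = sorted(round(m.score, 9) for m in mcode_modules(h))
            assert sizes_g == sizes_h and scores_g == scores_h


class TestGirvanNewman:
    def test_two_four_cliques_with_bridge(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        g.add_edge(0, 4)
        part, q = girvan_newman_modularity(g)
        assert len(part) == 2
        assert q == pytest.approx(12 / 13 - 0.5, abs=5e-4)

    def test_complete_graph_stays_whole(self):
        part, q = girvan_newman_modularity(nx.complete_graph(6))
        assert len(part) == 1 and q == pytest.approx(0.0)

    def test_two_disconnected_triangles(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        _, q = girvan_newman_modularity(g)
        assert q == pytest.approx(0.5)

    def test_never_exceeds_partition_optimum(self):
        # GN only explores its own dendrogram, so it can fall short of the
        # global optimum but must never exceed it
        def all_partitions(nodes):
            if not nodes:
                yield []
                return
            first, rest = nodes[0], nodes[1:]
            for part in all_partitions(rest):
                for i in range(len(part)):
                    yield part[:i] + [[first] + part[i]] + part[i + 1:]
                yield [[first]] + part

        rng = np.random.default_rng(5)
        agree = 0
        total = 0
        for _ in range(100):
            n = int(rng.integers(4, 8))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0:
                continue
            total += 1
            _, q_gn = girvan_newman_modularity(g)
            q_best = max(
                nx.community.modularity(g, [set(b) for b in part])
                for part in all_partitions(list(g.nodes))
            )
            assert q_gn <= q_best + 1e-9
            agree += abs(q_gn - q_best) < 1e-9
        assert agree / total > 0.4  # optimum reached on a fair share of graphs


class TestCentralityClasses:
    def test_table_of_printed_central_otus(self):
        rows = {
            "bn_000226": (60, 0.06, 0.43, "hub"),
            "en_00092": (42, 0.04, 0.42, "hub"),
            "bn_000059": (24, 0.03, 0.40, "hub"),
            "ep_00269": (2, 1.00, 1.00, "connector"),
            "bp_000001": (5, 0.05, 0.30, "connector"),
            "bn_000008": (5, 0.03, 0.27, "connector"),
            "mid_degree": (12, 0.5, 0.5, "none"),
            "low_bc": (30, 0.01, 0.5, "none"),
        }
        metrics = pd.DataFrame(
            {
                "degree": {k: v[0] for k, v in rows.items()},
                "betweenness": {k: v[1] for k, v in rows.items()},
                "closeness": {k: v[2] for k, v in rows.items()},
            }
        )
        classes = classify_central(metrics)
        for name, (_, _, _, expected) in rows.items():
            assert classes[name] == expected

    def test_hub_and_connector_mutually_exclusive(self):
        metrics = pd.DataFrame(
            {"degree": [5], "betweenness": [0.5], "closeness": [0.5]}, index=["x"]
        )
        # degree 5 with high centrality: connector only (not hub: degree < 24)
        assert classify_central(metrics)["x"] == "connector"
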