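import networkx as nx
import numpy as np
import pytest

from lncsubpath.pcst import extract_subpathways, objective, solve, solve_exact
from lncsubpath.weighting import WeightedPathway


def wp_from(graph, prizes, costs):
    return WeightedPathway.from_prizes(graph, prizes, costs)


def random_instance(seed, n_lo=6, n_hi=15):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_lo, n_hi + 1))
    g = nx.gnp_random_graph(n, 0.35, seed=int(rng.integers(0, 2**31)))
    prizes = {v: float(rng.uniform(0, 15)) for v in g.nodes}
    costs = {(u, v): float(rng.uniform(0, 1)) for u, v in g.edges}
    return wp_from(g, prizes, costs)


class TestObjective:
    def test_empty_solution_is_zero(self):
        g = nx.Graph([("a", "b")])
        assert objective([], [], wp_from(g, {"a": 1, "b": 1}, {("a", "b"): 0.5})) == 0.0

    def test_two_node_value(self):
        g = nx.Graph([("a", "b")])
        wp = wp_from(g, {"a": 5, "b": 5}, {("a", "b"): 0.3})
        assert objective(["a", "b"], [("a", "b")], wp) == pytest.approx(-9.7)

    def test_single_node(self):
        g = nx.Graph([("a", "b")])
        wp = wp_from(g, {"a": 12, "b": 0}, {("a", "b"): 0.5})
        assert objective(["a"], [], wp) == pytest.approx(-12.0)


class TestSolveExact:
    def test_path_instance_optimum(self):
        g = nx.Graph()
        nx.add_path(g, "abcd")
        wp = wp_from(g, {"a": 10, "b": 0.1, "c": 0.1, "d": 10},
                     {("a", "b"): 0.5, ("b", "c"): 0.5, ("c", "d"): 0.5})
        sol = solve_exact(wp)
        assert sol.nodes == ("a", "b", "c", "d")
        assert sol.objective == pytest.approx(-18.7)

    def test_zero_prizes_tie_breaks_lexicographically(self):
        g = nx.Graph()
        nx.add_path(g, ["c", "a", "b"])
        wp = wp_from(g, {v: 0.0 for v in "abc"}, {("c", "a"): 0.4, ("a", "b"): 0.4})
        sol = solve_exact(wp)
        assert sol.nodes == ("a",)
        assert sol.objective == 0.0

    def test_single_prize_node_alone_when_costs_high(self):
        g = nx.Graph()
        nx.add_path(g, "abc")
        wp = wp_from(g, {"a": 0, "b": 1, "c": 0}, {("a", "b"): 1.0, ("b", "c"): 1.2})
        sol = solve_exact(wp)
        assert sol.nodes == ("b",)
        assert sol.objective == pytest.approx(-1.0)

    def test_refuses_large_graphs(self):
        g = nx.path_graph(20)
        wp = wp_from(g, {v: 1.0 for v in g.nodes}, {e: 0.5 for e in g.edges})
        with pytest.raises(ValueError, match="max_nodes"):
            solve_exact(wp)


class TestSolve:
    def test_all_zero_prizes_reports_no_region(self):
        g = nx.path_graph(6)
        wp = wp_from(g, {v: 0.0 for v in g.nodes}, {e: 0.5 for e in g.edges})
        assert solve(wp) is None

    def test_costly_bridge_keeps_single_cluster(self):
        g = nx.Graph()
        left, right = ["a1", "a2", "a3", "a4", "a5"], ["b1", "b2", "b3", "b4"]
        nx.add_path(g, left)
        nx.add_path(g, right)
        g.add_edge("a5", "b1")  # bridge
        prizes = {v: 3.0 for v in left}
        prizes.update({v: 0.2 for v in right})
        costs = {e: 0.1 for e in g.edges}
        costs[("a5", "b1")] = 2.0  # pricier than everything beyond it
        sol = solve(wp_from(g, prizes, costs))
        assert set(sol.nodes) == set(left)

    def test_returned_edges_form_spanning_tree(self):
        for seed in range(30):
            wp = random_instance(seed)
            sol = solve(wp)
            if sol is None:
                continue
            t = nx.Graph(list(tuple(e) for e in sol.edges))
            t.add_nodes_from(sol.nodes)
            assert nx.is_tree(t)
            assert set(t.nodes) == set(sol.nodes)
            # tree edge costs match the MST of the induced subgraph
            induced = wp.pathway.graph.subgraph(sol.nodes)
            mst_cost = sum(
                wp.edge_cost[frozenset(e)]
                for e in nx.minimum_spanning_edges(
                    nx.Graph([(u, v, {"weight": wp.edge_cost[frozenset((u, v))]})
                              for u, v in induced.edges]), data=False)
            ) if induced.number_of_edges() else 0.0
            tree_cost = sum(wp.edge_cost[frozenset(e)] for e in sol.edges)
            assert tree_cost == pytest.approx(mst_cost, abs=1e-9)

    def test_objective_recomputable_from_parts(self):
        for seed in range(20):
            wp = random_instance(seed + 100)
            sol = solve(wp)
            if sol is None:
                continue
            assert sol.objective == pytest.approx(
                objective(sol.nodes, sol.edges, wp), abs=1e-9)

    def test_prize_and_cost_scaling_monotonicity(self):
        for seed in range(20):
            wp = random_instance(seed + 300)
            base = solve(wp)
            base_obj = base.objective if base else 0.0
            up = WeightedPathway.from_prizes(
                wp.pathway.graph,
                {v: 2.0 * p for v, p in wp.node_prize.items()},
                {tuple(e): c for e, c in wp.edge_cost.items()},
            )
            up_sol = solve(up)
            up_obj = up_sol.objective if up_sol else 0.0
            assert up_obj <= base_obj + 1e-9
            pricier = WeightedPathway.from_prizes(
                wp.pathway.graph,
                dict(wp.node_prize),
                {tuple(e): 2.0 * c for e, c in wp.edge_cost.items()},
            )
            pr_sol = solve(pricier)
            pr_obj = pr_sol.objective if pr_sol else 0.0
            assert pr_obj >= base_obj - 1e-9


class TestExtractSubpathways:
    def test_single_region_equals_solve(self):
        wp = random_instance(7)
        regions = extract_subpathways(wp, max_regions=1)
        sol = solve(wp)
        assert [r.nodes for r in regions] == ([sol.nodes] if sol else [])

    def test_two_planted_clusters_recovered_disjointly(self):
        # bridge edges cost more than the far cluster is worth, so the optimum
        # is one cluster at a time and iteration recovers both disjointly
        g = nx.Graph()
        nx.add_path(g, ["a1", "a2", "a3", "x1", "x2", "x3", "b1", "b2", "b3"])
        prizes = {v: (5.0 if v[0] in "ab" else 0.0) for v in g.nodes}
        costs = {e: 0.2 for e in g.edges}
        for e in [("a3", "x1"), ("x1", "x2"), ("x2", "x3"), ("x3", "b1")]:
            costs[e] = 6.0
        wp = wp_from(g, prizes, costs)
        regions = extract_subpathways(wp, max_regions=5)
        assert len(regions) == 2
        sets = [set(r.nodes) for r in regions]
        assert sets[0] & sets[1] == set()
        assert {"a1", "a2", "a3"} in sets and {"b1", "b2", "b3"} in sets

    def test_stops_when_no_profitable_region_remains(self):
        g = nx.path_graph(6)
        prizes = {v: (4.0 if v < 2 else 0.0) for v in g.nodes}
        wp = wp_from(g, prizes, {e: 0.8 for e in g.edges})
        regions = extract_subpathways(wp, max_regions=5)
        assert len(regions) == 1
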