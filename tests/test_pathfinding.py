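import itertools

import networkx as nx
import pytest

from channeltess import cluster_mcps, edge_cost, enumerate_mcps, minimal_cost_path
from channeltess.facial_graph import EXTERIOR_NODE
from tests.test_facial_graph import synthetic_graph


class TestEdgeCost:
    @pytest.mark.parametrize("cv, cvmax, expected", [
        (6, 6, 1.0),
        (6, 12, 0.5),
        (3, 12, 0.25),
    ])
    def test_values(self, cv, cvmax, expected):
        assert edge_cost(cv, cvmax) == pytest.approx(expected)

    def test_closed_door_is_a_contract_violation(self):
        with pytest.raises(ValueError):
            edge_cost(7, 6)
        with pytest.raises(ValueError):
            edge_cost(0, 6)


def brute_force_cost(fg, cv):
    """Minimum path cost by exhaustive simple-path enumeration."""
    g = nx.Graph()
    for u, v, d in fg.graph.edges(data=True):
        if d["cvmax"] >= cv:
            w = cv / d["cvmax"]
            if not g.has_edge(u, v) or g[u][v]["weight"] > w:
                g.add_edge(u, v, weight=w)
    best = None
    for t in fg.target_cells:
        if t not in g or EXTERIOR_NODE not in g:
            continue
        for path in nx.all_simple_paths(g, EXTERIOR_NODE, t):
            cost = sum(g[a][b]["weight"] for a, b in itertools.pairwise(path))
            if best is None or cost < best:
                best = cost
    return best


class TestMinimalCostPath:
    def test_diamond_prefers_cheaper_total(self):
        # top 0.5 + 0.5 = 1.0 beats bottom 0.4 + 0.9 = 1.3 at cv = 2
        fg = synthetic_graph(
            [("EXT", 1, 4.0), (1, 9, 4.0), ("EXT", 2, 5.0), (2, 9, 2 / 0.9)], {9})
        mcp = minimal_cost_path(fg, 2.0)
        assert mcp.cells == [1, 9]
        assert mcp.total_cost == pytest.approx(1.0)

    def test_single_path(self):
        fg = synthetic_graph([("EXT", 1, 8), (1, 2, 6)], {2})
        mcp = minimal_cost_path(fg, 3.0)
        assert mcp.cells == [1, 2]
        assert mcp.edges == [0, 1]
        assert mcp.total_cost == pytest.approx(3 / 8 + 3 / 6)

    def test_no_path_returns_none(self):
        fg = synthetic_graph([("EXT", 1, 8)], {2})
        assert minimal_cost_path(fg, 3.0) is None

    def test_optimal_on_random_graphs_vs_enumeration(self, rng):
        checked = 0
        for _ in range(60):
            n = int(rng.integers(4, 12))
            edges = [("EXT", 0, float(rng.uniform(2, 10)))]
            for _ in range(int(rng.integers(n, 3 * n))):
                u, v = rng.integers(0, n, 2)
                if u != v:
                    edges.append((int(u), int(v), float(rng.uniform(2, 10))))
            fg = synthetic_graph(edges, {n - 1})
            cv = float(rng.uniform(1.0, 3.0))
            mcp = minimal_cost_path(fg, cv)
            expected = brute_force_cost(fg, cv)
            if expected is None:
                assert mcp is None
            else:
                checked += 1
                assert mcp.total_cost == pytest.approx(expected, rel=1e-12)
        assert checked >= 50

    def test_cost_recomputes_from_edges(self, two_pore_bundle):
        _, _, tess, fg = two_pore_bundle
        mcp = minimal_cost_path(fg, 3.0)
        recomputed = sum(3.0 / tess.faces[fid].cvmax for fid in mcp.edges)
        assert mcp.total_cost == pytest.approx(recomputed, rel=1e-12)
        assert all(tess.faces[fid].cvmax >= 3.0 for fid in mcp.edges)


class TestEnumerateMcps:
    def test_two_disjoint_paths_found(self):
        fg = synthetic_graph(
            [("EXT", 1, 8), (1, 9, 8), ("EXT", 2, 6), (2, 9, 6)], {9})
        mcps = enumerate_mcps(fg, 2.0)
        assert len(mcps) == 2
        assert [m.rank for m in mcps] == [1, 2]
        used = [set(m.edges) for m in mcps]
        assert used[0].isdisjoint(used[1])

    def test_single_path_graph_terminates_after_one(self):
        fg = synthetic_graph([("EXT", 1, 8), (1, 2, 6)], {2})
        assert len(enumerate_mcps(fg, 2.0)) == 1

    def test_max_paths_caps_extraction(self):
        fg = synthetic_graph(
            [("EXT", 1, 8), (1, 9, 8), ("EXT", 2, 6), (2, 9, 6)], {9})
        assert len(enumerate_mcps(fg, 2.0, max_paths=1)) == 1

    def test_menger_bound_on_random_graphs(self, rng):
        # iterative edge removal can never extract more edge-disjoint
        # paths than the max-flow bound with unit capacities
        for _ in range(30):
            n = int(rng.integers(4, 10))
            edges = [("EXT", 0, 5.0)]
            for _ in range(int(rng.integers(n, 4 * n))):
                u, v = rng.integers(0, n, 2)
                if u != v:
                    edges.append((int(u), int(v), float(rng.uniform(2, 10))))
            fg = synthetic_graph(edges, {n - 1, n - 2})
            cv = 1.5
            mcps = enumerate_mcps(fg, cv)
            flow = nx.DiGraph()
            for u, v, d in fg.graph.edges(data=True):
                if d["cvmax"] >= cv:
                    flow.add_edge(u, v, capacity=flow.get_edge_data(u, v, {"capacity": 0})["capacity"] + 1)
                    flow.add_edge(v, u, capacity=flow.get_edge_data(v, u, {"capacity": 0})["capacity"] + 1)
            for t in fg.target_cells:
                if t in flow:
                    flow.add_edge(t, "SINK", capacity=10 ** 6)
            if EXTERIOR_NODE in flow and "SINK" in flow:
                bound = nx.maximum_flow_value(flow, EXTERIOR_NODE, "SINK")
            else:
                bound = 0
            assert len(mcps) <= bound

    def test_determinism_under_node_relabelling(self, rng):
        edges = [("EXT", 0, 5.0), (0, 1, 6.0), (1, 4, 7.0), (0, 2, 6.0),
                 (2, 4, 7.0), (0, 3, 6.0), (3, 4, 7.0)]
        fg = synthetic_graph(edges, {4})
        ref = [tuple(m.cells) for m in enumerate_mcps(fg, 2.0)]
        shuffled = synthetic_graph(list(reversed(edges)), {4})
        assert [tuple(m.cells) for m in enumerate_mcps(shuffled, 2.0)] == ref
        # equal-cost parallel branches resolve to the smallest cell ids first
        assert ref[0] == (0, 1, 4)


class TestClusterMcps:
    def test_overlapping_paths_merge(self, two_pore_bundle):
        _, _, tess, fg = two_pore_bundle
        mcps = enumerate_mcps(fg, 3.9)
        trajs = cluster_mcps(mcps, tess)
        assert len(mcps) == 2
        assert len(trajs) == 2
        assert all(len(t.member_mcps) == 1 for t in trajs)

    def test_disjoint_paths_stay_separate(self, two_pore_bundle):
        _, _, tess, _ = two_pore_bundle
        from channeltess.pathfinding import MCP
        a = MCP(cv=1, edges=[], cells=[0, 1, 2], total_cost=0.1, rank=1)
        b = MCP(cv=1, edges=[], cells=[5, 6, 7], total_cost=0.2, rank=2)
        assert len(cluster_mcps([a, b], tess)) == 2

    def test_single_linkage_chains(self, two_pore_bundle):
        _, _, tess, _ = two_pore_bundle
        from channeltess.pathfinding import MCP
        a = MCP(cv=1, edges=[], cells=[0, 1, 2, 3], total_cost=0.1, rank=1)
        b = MCP(cv=1, edges=[], cells=[2, 3, 4, 5], total_cost=0.2, rank=2)
        c = MCP(cv=1, edges=[], cells=[4, 5, 6, 7], total_cost=0.3, rank=3)
        # a~b and b~c overlap (Jaccard 1/3), a~c do not: one chained cluster
        trajs = cluster_mcps([a, b, c], tess)
        assert len(trajs) == 1
        assert {m.rank for m in trajs[0].member_mcps} == {1, 2, 3}

    def test_threshold_validation(self, two_pore_bundle):
        _, _, tess, _ = two_pore_bundle
        with pytest.raises(ValueError):
            cluster_mcps([], tess, overlap_threshold=0.0)
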