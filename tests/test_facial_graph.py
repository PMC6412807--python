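import networkx as nx
import numpy as np
import pytest

from channeltess import (
    EXTERIOR_NODE,
    FacialGraph,
    annotate_cvmax,
    build_graph,
    channels_at,
    compute_cvlim,
    cv_profile,
    graph_at,
    triangulate,
    widest_path_cvlim,
)
from tests.test_tessellation import PAIR_POINTS, UNIT_CORNER, _atoms


def synthetic_graph(edges, target_cells):
    """FacialGraph from (u, v, cvmax) triples; 'EXT' maps to the exterior node."""
    g = nx.MultiGraph()
    for i, (u, v, cvmax) in enumerate(edges):
        u = EXTERIOR_NODE if u == "EXT" else u
        v = EXTERIOR_NODE if v == "EXT" else v
        g.add_edge(u, v, key=i, cvmax=float(cvmax), face_id=i)
    g.add_node(EXTERIOR_NODE)
    return FacialGraph(graph=g, target_cells=frozenset(target_cells), tess=None)


@pytest.fixture()
def two_tetra_graph():
    tess = annotate_cvmax(triangulate(_atoms(PAIR_POINTS,
                                             radius=0.05)))
    return tess, build_graph(tess, 0)


class TestBuildGraph:
    def test_two_tetra_counts(self, two_tetra_graph):
        tess, fg = two_tetra_graph
        g = fg.graph
        assert fg.n_cells == 2
        internal = [e for e in g.edges if EXTERIOR_NODE not in e[:2]]
        assert len(internal) == 1
        assert g.degree(EXTERIOR_NODE) == len(tess.hull_face_ids) == 6

    def test_target_star_of_shared_vertex(self, two_tetra_graph):
        tess, _ = two_tetra_graph
        # atom 1 (vertex (1,0,0)) belongs to both cells
        fg = build_graph(tess, 1)
        assert fg.target_cells == frozenset({0, 1})

    def test_target_point_inside_cell(self, two_tetra_graph):
        tess, _ = two_tetra_graph
        fg = build_graph(tess, np.array([0.1, 0.1, 0.1]))
        assert len(fg.target_cells) == 1

    def test_target_point_outside_hull_is_an_error(self, two_tetra_graph):
        tess, _ = two_tetra_graph
        with pytest.raises(ValueError, match="outside the convex hull"):
            build_graph(tess, np.array([10.0, 10.0, 10.0]))

    def test_unused_target_atom_is_an_error(self, two_tetra_graph):
        tess, _ = two_tetra_graph
        with pytest.raises(ValueError, match="not a tessellation vertex"):
            build_graph(tess, 99)


class TestGraphAt:
    def test_threshold_nesting(self):
        fg = synthetic_graph(
            [("EXT", 1, 8), (1, 2, 6), (2, 3, 9), (1, 3, 2)], {3})
        for cv1, cv2 in [(1, 5), (5, 7), (7, 10)]:
            e1 = set(graph_at(fg, cv1).edges)
            e2 = set(graph_at(fg, cv2).edges)
            assert e2 <= e1
        assert len(graph_at(fg, 100).edges) == 0

    def test_invalid_cv(self):
        fg = synthetic_graph([("EXT", 1, 8)], {1})
        with pytest.raises(ValueError):
            graph_at(fg, 0)


class TestCvlim:
    def test_chain_bottleneck(self):
        fg = synthetic_graph([("EXT", 1, 8), (1, 2, 6), (2, 3, 9)], {3})
        assert compute_cvlim(fg) == pytest.approx(6.0)

    def test_parallel_paths_take_the_wider(self):
        fg = synthetic_graph(
            [("EXT", 1, 5), (1, 9, 5), ("EXT", 2, 7), (2, 9, 8)], {9})
        assert compute_cvlim(fg) == pytest.approx(7.0)

    def test_unreachable_target_returns_zero(self):
        fg = synthetic_graph([("EXT", 1, 8), (2, 3, 5)], {3})
        assert compute_cvlim(fg) == 0.0
        assert widest_path_cvlim(fg) == 0.0

    def test_bisection_equals_widest_path_on_random_graphs(self, rng):
        # the two independent CVlim algorithms must agree everywhere
        for _ in range(60):
            n = rng.integers(4, 12)
            edges = []
            for _ in range(rng.integers(n, 3 * n)):
                u, v = rng.integers(0, n, 2)
                if u == v:
                    continue
                edges.append((int(u), int(v), float(rng.uniform(0.5, 10))))
            edges.append(("EXT", 0, float(rng.uniform(0.5, 10))))
            fg = synthetic_graph(edges, {int(n - 1)})
            assert compute_cvlim(fg) == pytest.approx(widest_path_cvlim(fg))


class TestChannels:
    def test_shell_pore_single_channel_below_aperture(self, shell_bundle):
        _, _, _, fg = shell_bundle
        access = [c for c in channels_at(fg, 3.0) if c.is_access_channel]
        assert len(access) == 1

    def test_shell_pore_no_channel_above_aperture(self, shell_bundle):
        _, _, _, fg = shell_bundle
        cvlim = compute_cvlim(fg)
        access = [c for c in channels_at(fg, cvlim + 0.3) if c.is_access_channel]
        assert access == []

    def test_simplex_with_vertex_target_is_trivially_connected(self):
        tess = annotate_cvmax(triangulate(_atoms(UNIT_CORNER, radius=0.01)))
        fg = build_graph(tess, 0)
        access = [c for c in channels_at(fg, 0.05) if c.is_access_channel]
        assert len(access) == 1

    def test_channel_nesting_across_cv(self, shell_bundle):
        _, _, _, fg = shell_bundle
        big = [c for c in channels_at(fg, 1.0) if c.is_access_channel]
        small = [c for c in channels_at(fg, 3.0) if c.is_access_channel]
        assert small and big
        assert any(s.cells <= b.cells for b in big for s in small)


class TestProfile:
    def test_two_pore_ordered_events(self, two_pore_bundle):
        _, _, _, fg = two_pore_bundle
        rows = cv_profile(fg, list(np.arange(5.0, 0.9, -0.25)))
        events = [r.cv for r in rows if r.new_channels]
        assert len(events) == 2
        assert events[0] > events[1]
        # first channel tracks the wide aperture, second the narrow one
        assert events[0] == pytest.approx(8.0 - 3.4, abs=0.5)
        assert events[1] == pytest.approx(7.5 - 3.4, abs=0.5)

    def test_grid_must_be_descending_and_positive(self, two_pore_bundle):
        _, _, _, fg = two_pore_bundle
        with pytest.raises(ValueError):
            cv_profile(fg, [1.0, 2.0])
        with pytest.raises(ValueError):
            cv_profile(fg, [2.0, -1.0])
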