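"""Minimal cost paths (MCPs) from the exterior to the active site.

Within the funnel-like voids detected at a given ligand thickness CV,
preferential routes are extracted as minimal cost paths: each passable
door (edge) costs CV/CVmax, a number in (0, 1] that is small for wide
doors, and Dijkstra's algorithm finds the cheapest exterior-to-target
path.  Further routes are found iteratively: all edges of the current
MCP are removed and Dijkstra is run again until no path remains, so the
extracted MCPs are pairwise edge-disjoint.

MCPs are then clustered (single linkage on the Jaccard similarity of
their cell sets); each cluster is a trajectory — one channel in the
egress-route nomenclature sense.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import networkx as nx

from .facial_graph import EXTERIOR_NODE, FacialGraph
from .tessellation import Tessellation

__all__ = [
    "MCP",
    "Trajectory",
    "edge_cost",
    "minimal_cost_path",
    "enumerate_mcps",
    "cluster_mcps",
]

#: Default Jaccard similarity (on cell sets) above which two MCPs are
#: considered to follow the same trajectory.
DEFAULT_OVERLAP_THRESHOLD = 0.3


@dataclass
class MCP:
    """One minimal cost path, exterior -> target, at thickness ``cv``."""

    cv: float
    edges: list[int]        # face ids, in traversal order
    cells: list[int]        # tetra ids, in traversal order
    total_cost: float
    rank: int = 0

    @property
    def cell_set(self) -> frozenset[int]:
        return frozenset(self.cells)


@dataclass
class Trajectory:
    """A cluster of MCPs; corresponds to one named access channel."""

    member_mcps: list[MCP]
    cells: frozenset[int]
    volume: float = 0.0
    boundary_surface: float = 0.0
    lining: list = field(default_factory=list)
    egress: list = field(default_factory=list)

    @property
    def cv(self) -> float:
        return self.member_mcps[0].cv


def edge_cost(cv: float, cvmax: float) -> float:
    """The door-crossing cost CV/CVmax, in (0, 1]."""
    if cv <= 0:
        raise ValueError("cv must be positive")
    if cv > cvmax:
        raise ValueError(f"door with cvmax={cvmax} is closed at cv={cv}")
    return cv / cvmax


def _working_graph(fg: FacialGraph, cv: float) -> nx.MultiGraph:
    """Mutable copy of the facial graph keeping only doors open at cv."""
    g = nx.MultiGraph()
    g.add_nodes_from(fg.graph.nodes)
    for u, v, k, data in fg.graph.edges(keys=True, data=True):
        if data["cvmax"] >= cv:
            g.add_edge(u, v, key=k, **data)
    return g


def _dijkstra(g: nx.MultiGraph, cv: float, targets: frozenset[int]) -> MCP | None:
    """Deterministic Dijkstra from EXTERIOR to any target cell.

    Labels are compared as (total cost, number of edges, cell-id
    sequence), so ties resolve to the path with fewer doors, then to the
    lexicographically smallest cell sequence.  The multiple target cells
    act as a zero-cost virtual sink: the first target finalised carries
    the overall minimum.
    """
    if EXTERIOR_NODE not in g:
        return None
    start_key = (0.0, 0, (EXTERIOR_NODE,))
    best: dict = {EXTERIOR_NODE: start_key}
    edges_of: dict = {EXTERIOR_NODE: ()}
    heap = [start_key + (EXTERIOR_NODE,)]
    done = set()
    while heap:
        cost, nedges, path, u = heapq.heappop(heap)
        if u in done or (cost, nedges, path) != best.get(u):
            continue
        done.add(u)
        if u in targets:
            return MCP(
                cv=cv,
                edges=list(edges_of[u]),
                cells=list(path[1:]),
                total_cost=cost,
            )
        for v, keyed in g[u].items():
            if v in done or v == EXTERIOR_NODE:
                continue
            # parallel doors: cross the widest (cheapest), tie -> smallest face id
            k, data = min(keyed.items(), key=lambda kd: (cv / kd[1]["cvmax"], kd[0]))
            key = (cost + edge_cost(cv, data["cvmax"]), nedges + 1, path + (v,))
            if v not in best or key < best[v]:
                best[v] = key
                edges_of[v] = edges_of[u] + (data["face_id"],)
                heapq.heappush(heap, key + (v,))
    return None


def minimal_cost_path(fg: FacialGraph, cv: float) -> MCP | None:
    """The cheapest exterior-to-target path at thickness cv, or None."""
    return _dijkstra(_working_graph(fg, cv), cv, fg.target_cells)


def enumerate_mcps(fg: FacialGraph, cv: float, max_paths: int | None = None) -> list[MCP]:
    """Iteratively extract edge-disjoint MCPs.

    After each extraction all edges of the current MCP are removed from
    the working graph and Dijkstra is rerun; the edge set strictly
    decreases, so the iteration terminates.
    """
    g = _working_graph(fg, cv)
    face_edges = {
        data["face_id"]: (u, v, k)
        for u, v, k, data in g.edges(keys=True, data=True)
    }
    mcps: list[MCP] = []
    while max_paths is None or len(mcps) < max_paths:
        mcp = _dijkstra(g, cv, fg.target_cells)
        if mcp is None:
            break
        mcp.rank = len(mcps) + 1
        mcps.append(mcp)
        for fid in mcp.edges:
            g.remove_edge(*face_edges[fid])
    return mcps


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def cluster_mcps(
    mcps: list[MCP],
    tess: Tessellation,
    overlap_threshold: float = DEFAULT_OVERLAP_THRESHOLD,
) -> list[Trajectory]:
    """Single-linkage clustering of MCPs into trajectories.

    Two MCPs join the same cluster whenever a chain of pairwise Jaccard
    similarities >= ``overlap_threshold`` links them (connected
    components of the similarity graph).  Output is sorted by cluster
    volume descending.
    """
    if not 0 < overlap_threshold <= 1:
        raise ValueError("overlap_threshold must be in (0, 1]")
    from .measures import region_boundary_surface, region_volume

    n = len(mcps)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _jaccard(mcps[i].cell_set, mcps[j].cell_set) >= overlap_threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[MCP]] = {}
    for i, mcp in enumerate(mcps):
        groups.setdefault(find(i), []).append(mcp)

    trajectories = []
    for members in groups.values():
        cells = frozenset().union(*(m.cell_set for m in members))
        trajectories.append(Trajectory(
            member_mcps=sorted(members, key=lambda m: m.rank),
            cells=cells,
            volume=region_volume(cells, tess),
            boundary_surface=region_boundary_surface(cells, tess, members[0].cv),
        ))
    trajectories.sort(key=lambda t: (-t.volume, min(t.cells)))
    return trajectories
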