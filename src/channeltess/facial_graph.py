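"""The facial graph: cells as nodes, passable doors as edges.

Every tetrahedral cell is a node; the triangular face between two
adjacent cells is an edge carrying that door's CVmax.  A single EXTERIOR
super-node is attached through every hull face (a ligand enters wherever
a hull door is wide enough).  The target cells are the cells incident to
the target atom (for the heme iron, its whole star of cells), or the one
cell containing a literal target point.

At a given ligand thickness CV the graph keeps exactly the edges with
CVmax >= CV; any connected component of cells linking the EXTERIOR to a
target cell is a channel.  The largest CV for which a channel still
exists is CVlim — the bottleneck (widest-path) value over all
exterior-to-target paths.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import Delaunay

from .tessellation import EXTERIOR, Tessellation

__all__ = [
    "EXTERIOR_NODE",
    "FacialGraph",
    "Channel",
    "ProfileRow",
    "build_graph",
    "graph_at",
    "channels_at",
    "compute_cvlim",
    "widest_path_cvlim",
    "cv_profile",
]

#: Node label of the exterior super-node in the facial graph.
EXTERIOR_NODE = "EXTERIOR"


@dataclass
class FacialGraph:
    graph: nx.MultiGraph
    target_cells: frozenset[int]
    tess: Tessellation

    @property
    def n_cells(self) -> int:
        return self.graph.number_of_nodes() - 1


@dataclass
class Channel:
    """One connected component of the CV-thresholded facial graph."""

    cv: float
    cells: frozenset[int]
    reaches_exterior: bool
    reaches_target: bool

    @property
    def is_access_channel(self) -> bool:
        return self.reaches_exterior and self.reaches_target

    def volume(self, tess: Tessellation) -> float:
        return sum(tess.tetrahedra[c].volume for c in self.cells)


@dataclass
class ProfileRow:
    cv: float
    n_channels: int
    volumes: list[float]
    new_channels: int = 0


def build_graph(tess: Tessellation, target: int | np.ndarray) -> FacialGraph:
    """Build the facial graph of an annotated tessellation.

    ``target`` is either the index of the target atom in the tessellated
    point set (its incident cells become the target cells) or a literal
    point (the cell containing it becomes the target cell).
    """
    g = nx.MultiGraph()
    g.add_nodes_from(t.id for t in tess.tetrahedra)
    g.add_node(EXTERIOR_NODE)
    for face in tess.faces:
        if np.isnan(face.cvmax):
            raise ValueError("faces are not annotated with cvmax; run annotate_cvmax")
        c1, c2 = face.cells
        v = c2 if c2 != EXTERIOR else EXTERIOR_NODE
        # MultiGraph keyed by face id: a cell may expose several hull doors
        g.add_edge(c1, v, key=face.id, cvmax=face.cvmax, face_id=face.id)

    if isinstance(target, (int, np.integer)):
        idx = int(target)
        cells = frozenset(
            t.id for t in tess.tetrahedra if idx in t.vertex_atoms
        )
        if not cells:
            raise ValueError(f"target atom index {idx} is not a tessellation vertex")
    else:
        point = np.asarray(target, dtype=float).reshape(3)
        tri = Delaunay(tess.points)
        simplex = int(tri.find_simplex(point))
        if simplex < 0:
            raise ValueError(f"target point {point.tolist()} lies outside the convex hull")
        # map backend simplex to our tetra id via the sorted vertex tuple
        triple = tuple(sorted(int(v) for v in tri.simplices[simplex]))
        cells = frozenset(
            t.id for t in tess.tetrahedra if t.vertex_atoms == triple
        )
        if not cells:  # pragma: no cover - triangulations should agree
            raise ValueError("could not locate the cell containing the target point")
    return FacialGraph(graph=g, target_cells=cells, tess=tess)


def graph_at(fg: FacialGraph, cv: float) -> nx.MultiGraph:
    """Read-only view keeping exactly the edges with cvmax >= cv."""
    if cv <= 0:
        raise ValueError("cv must be positive")
    g = fg.graph
    return nx.subgraph_view(
        g, filter_edge=lambda u, v, k: g[u][v][k]["cvmax"] >= cv
    )


def channels_at(fg: FacialGraph, cv: float) -> list[Channel]:
    """Connected cell components at thickness CV, access channels first.

    Components linking the exterior to the active site come first,
    sorted by volume descending (ties: smallest cell id); the remaining
    components (pockets, pores, isolated voids) follow in the same
    order.
    """
    gv = graph_at(fg, cv)
    ext_adjacent = set(gv.neighbors(EXTERIOR_NODE))
    cells_only = nx.subgraph_view(gv, filter_node=lambda n: n != EXTERIOR_NODE)
    channels = []
    for comp in nx.connected_components(cells_only):
        cells = frozenset(comp)
        channels.append(Channel(
            cv=cv,
            cells=cells,
            reaches_exterior=bool(cells & ext_adjacent),
            reaches_target=bool(cells & fg.target_cells),
        ))
    tess = fg.tess
    channels.sort(key=lambda ch: (
        not ch.is_access_channel,
        -ch.volume(tess),
        min(ch.cells),
    ))
    return channels


def _has_channel(fg: FacialGraph, cv: float) -> bool:
    gv = graph_at(fg, cv)
    seen = {EXTERIOR_NODE}
    stack = [EXTERIOR_NODE]
    while stack:
        u = stack.pop()
        for v in gv.neighbors(u):
            if v not in seen:
                if v in fg.target_cells:
                    return True
                seen.add(v)
                stack.append(v)
    return bool(fg.target_cells & seen)


def compute_cvlim(fg: FacialGraph) -> float:
    """CVlim by binary search over the distinct door widths.

    Channel existence is monotone in CV, so CVlim is the largest distinct
    CVmax value at which the exterior still reaches a target cell.
    Returns 0 when the target is unreachable at any positive CV.
    """
    values = sorted({d["cvmax"] for _, _, d in fg.graph.edges(data=True) if d["cvmax"] > 0})
    if not values:
        return 0.0
    lo, hi = 0, len(values) - 1
    if not _has_channel(fg, values[0]):
        return 0.0
    best = values[0]
    while lo <= hi:
        mid = (lo + hi) // 2
        if _has_channel(fg, values[mid]):
            best = values[mid]
            lo = mid + 1
        else:
            hi = mid - 1
    return float(best)


def widest_path_cvlim(fg: FacialGraph) -> float:
    """CVlim by a max-min (widest-path) variant of Dijkstra.

    Independent cross-check of :func:`compute_cvlim`: grows paths from
    the EXTERIOR maximising the minimum edge CVmax along the path.
    """
    g = fg.graph
    width = {EXTERIOR_NODE: np.inf}
    heap = [(-np.inf, 0, EXTERIOR_NODE)]  # (-bottleneck, tiebreak, node)
    count = 0
    seen = set()
    while heap:
        negw, _, u = heapq.heappop(heap)
        if u in seen:
            continue
        seen.add(u)
        w_u = -negw
        if u in fg.target_cells:
            return float(w_u) if np.isfinite(w_u) else 0.0
        for v, keyed in g[u].items():
            if v in seen:
                continue
            w = min(w_u, max(d["cvmax"] for d in keyed.values()))
            if w > width.get(v, 0.0):
                width[v] = w
                count += 1
                heapq.heappush(heap, (-w, count, v))
    return 0.0


def cv_profile(fg: FacialGraph, cv_grid: list[float]) -> list[ProfileRow]:
    """Channel census over a descending CV grid.

    For each CV the access channels (exterior-to-target components) are
    counted with their volumes.  A "new channel" event is recorded when
    an access channel appears whose cells are disjoint from every access
    channel already seen at a higher CV — the bookkeeping behind "the
    first channel appears at CVlim and the next channels appear at
    CV < CVlim".
    """
    grid = list(cv_grid)
    if any(cv <= 0 for cv in grid):
        raise ValueError("cv grid values must be positive")
    if grid != sorted(grid, reverse=True):
        raise ValueError("cv grid must be sorted descending")
    seen_channels: list[frozenset[int]] = []
    rows = []
    for cv in grid:
        access = [ch for ch in channels_at(fg, cv) if ch.is_access_channel]
        new = 0
        for ch in access:
            if all(not (ch.cells & prev) for prev in seen_channels):
                new += 1
                seen_channels.append(ch.cells)
        rows.append(ProfileRow(
            cv=cv,
            n_channels=len(access),
            volumes=[ch.volume(fg.tess) for ch in access],
            new_channels=new,
        ))
    return rows
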