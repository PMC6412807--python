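"""Quantifying tetrahedron sets: volume, boundary surface, void partition.

A channel, MCP or trajectory is a set of tetrahedral cells.  Its volume
is the sum of the cell volumes.  Its boundary is the set of triangular
faces, incident to the set, that the ligand cannot pass (CVmax < CV);
passable faces are openings and contribute no boundary even on the rim
of the set, so a fully open path has zero bounding surface.
"""

from __future__ import annotations

from collections import deque
from typing import Iterable

from .facial_graph import Channel
from .structure_io import AtomCategory
from .tessellation import EXTERIOR, Tessellation

__all__ = ["region_volume", "region_boundary_surface", "classify_void"]


def region_volume(cells: Iterable[int], tess: Tessellation) -> float:
    """Sum of the volumes (Å³) of the given cells."""
    return float(sum(tess.tetrahedra[c].volume for c in set(cells)))


def region_boundary_surface(cells: Iterable[int], tess: Tessellation, cv: float) -> float:
    """Total area (Å²) of the closed faces incident to the cell set.

    A closed internal face shared by two cells of the set is one wall
    and is counted once.
    """
    cell_set = set(cells)
    area = 0.0
    seen: set[int] = set()
    for c in cell_set:
        for fid in tess.faces_of_tetra[c]:
            if fid in seen:
                continue
            seen.add(fid)
            face = tess.faces[fid]
            if face.cvmax < cv:
                area += face.area
    return float(area)


def classify_void(channel: Channel, tess: Tessellation) -> tuple[float, float]:
    """Volume fractions of a channel that are surface pocket vs active site.

    Channels of buried-site proteins typically include a wide mouth
    cavity lying at the protein surface; this partitions the channel
    cells into

    * "surface" cells: cells with at least one hull face, plus cells
      connected to those through cells that keep at least one vertex
      atom on the convex hull;
    * "active-site" cells: non-surface cells with a vertex atom in the
      cofactor (heme) residue;
    * the remaining transit cells.

    Returns (surface_fraction, active_site_fraction), volume-weighted;
    their sum is <= 1 and the remainder is transit.
    """
    cells = set(channel.cells)
    if not cells:
        raise ValueError("channel has no cells")
    hull_atoms = tess.hull_vertex_atoms()

    hull_face_cells = set()
    for fid in tess.hull_face_ids:
        c = tess.faces[fid].cells[0]
        if c in cells:
            hull_face_cells.add(c)

    def touches_hull(c: int) -> bool:
        return any(v in hull_atoms for v in tess.tetrahedra[c].vertex_atoms)

    # flood from hull-face cells through hull-touching cells of the channel
    surface = set(hull_face_cells)
    queue = deque(c for c in hull_face_cells if touches_hull(c))
    adjacency: dict[int, set[int]] = {c: set() for c in cells}
    for c in cells:
        for fid in tess.faces_of_tetra[c]:
            c1, c2 = tess.faces[fid].cells
            other = c2 if c1 == c else c1
            if other != EXTERIOR and other in cells:
                adjacency[c].add(other)
    while queue:
        c = queue.popleft()
        for other in adjacency[c]:
            if other not in surface and touches_hull(other):
                surface.add(other)
                queue.append(other)

    cofactor_atoms = {
        i for i, a in enumerate(tess.atoms) if a.category == AtomCategory.COFACTOR
    }
    active = {
        c for c in cells - surface
        if any(v in cofactor_atoms for v in tess.tetrahedra[c].vertex_atoms)
    }

    total = region_volume(cells, tess)
    if total == 0:
        return 0.0, 0.0
    return (
        region_volume(surface, tess) / total,
        region_volume(active, tess) / total,
    )
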