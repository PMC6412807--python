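"""Delaunay tetrahedral decomposition of the heavy-atom point set.

The convex hull of the heavy atoms is partitioned into non-overlapping
tetrahedral cells with atoms at their vertices.  Each pair of adjacent
cells shares a triangular face — a "door" the ligand may or may not pass —
and hull faces open onto the exterior.  This module builds that cell/face
topology; passability of the doors is computed in :mod:`channeltess.passage`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, QhullError

from .structure_io import AtomRecord

__all__ = [
    "EXTERIOR",
    "Tetrahedron",
    "Face",
    "Tessellation",
    "triangulate",
    "tetra_volume",
    "face_area",
]

#: Sentinel cell id for the outside of the convex hull.
EXTERIOR = -1

#: Magnitude (Å) of the deterministic jitter applied when the triangulation
#: backend reports a degenerate input.
DEGENERACY_JITTER = 1e-6
DEGENERACY_SEED = 20190225


@dataclass(slots=True)
class Tetrahedron:
    id: int
    vertex_atoms: tuple[int, int, int, int]
    volume: float
    barycenter: np.ndarray


@dataclass(slots=True)
class Face:
    """A triangular door between two cells (or a cell and the exterior)."""

    id: int
    vertex_atoms: tuple[int, int, int]
    cells: tuple[int, int]  # second entry may be EXTERIOR
    area: float
    cvmax: float = np.nan

    @property
    def is_hull(self) -> bool:
        return self.cells[1] == EXTERIOR


@dataclass
class Tessellation:
    atoms: list[AtomRecord]
    points: np.ndarray
    radii: np.ndarray
    tetrahedra: list[Tetrahedron]
    faces: list[Face]
    hull_face_ids: set[int]
    face_of_triple: dict[tuple[int, int, int], int] = field(default_factory=dict)
    faces_of_tetra: dict[int, list[int]] = field(default_factory=dict)
    jitter_applied: bool = False

    @property
    def n_cells(self) -> int:
        return len(self.tetrahedra)

    def hull_volume(self) -> float:
        return float(ConvexHull(self.points).volume)

    def hull_vertex_atoms(self) -> set[int]:
        return set(map(int, ConvexHull(self.points).vertices))

    def region_cells(self) -> set[int]:
        return {t.id for t in self.tetrahedra}

    def dump(self) -> str:
        """Debug text dump: one tetrahedron per line (id + 4 atom serials)."""
        lines = []
        for t in self.tetrahedra:
            serials = " ".join(str(self.atoms[i].serial) for i in t.vertex_atoms)
            lines.append(f"{t.id} {serials}")
        return "\n".join(lines) + "\n"


def tetra_volume(p1, p2, p3, p4) -> float:
    """|det(p2-p1, p3-p1, p4-p1)| / 6 in Å³; degenerate input gives 0."""
    p1 = np.asarray(p1, dtype=float)
    m = np.stack([np.asarray(p2) - p1, np.asarray(p3) - p1, np.asarray(p4) - p1])
    return abs(float(np.linalg.det(m))) / 6.0


def face_area(p1, p2, p3) -> float:
    """Triangle area ||(p2-p1) x (p3-p1)|| / 2 in Å²."""
    p1 = np.asarray(p1, dtype=float)
    cross = np.cross(np.asarray(p2, dtype=float) - p1, np.asarray(p3, dtype=float) - p1)
    return float(np.linalg.norm(cross)) / 2.0


def _tetra_volumes(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    p = points[simplices]
    m = p[:, 1:] - p[:, :1]
    return np.abs(np.linalg.det(m)) / 6.0


def triangulate(atoms: Sequence[AtomRecord]) -> Tessellation:
    """Build the Delaunay tessellation with full face adjacency.

    Near-degenerate inputs (e.g. many exactly cospherical points) are
    handled by a deterministic seeded jitter of magnitude 1e-6 Å, applied
    only when the backend reports degeneracy.
    """
    atoms = list(atoms)
    if len(atoms) < 4:
        raise ValueError("at least 4 atoms are required for a 3D tessellation")
    points = np.array([a.coords for a in atoms], dtype=float)
    radii = np.array([a.vdw_radius for a in atoms], dtype=float)

    # exactly flat input cannot be fixed by the degeneracy jitter
    centered = points - points.mean(axis=0)
    extent = np.linalg.svd(centered, compute_uv=False)[-1]
    if extent < 1e-9 * max(1.0, np.abs(points).max()):
        raise ValueError("points are coplanar; no 3D tessellation exists")

    jitter_applied = False
    try:
        tri = Delaunay(points)
        if tri.simplices.shape[0] == 0:
            raise QhullError("empty triangulation")
    except QhullError:
        rng = np.random.default_rng(DEGENERACY_SEED)
        points = points + rng.normal(scale=DEGENERACY_JITTER, size=points.shape)
        jitter_applied = True
        try:
            tri = Delaunay(points)
        except QhullError as exc:  # pragma: no cover - pathological input
            raise ValueError(f"degenerate point set (after jitter): {exc}") from exc
        if tri.simplices.shape[0] == 0:
            raise ValueError("degenerate (coplanar) point set")

    simplices = np.sort(tri.simplices, axis=1)
    volumes = _tetra_volumes(points, simplices)
    barycenters = points[simplices].mean(axis=1)

    tetrahedra = [
        Tetrahedron(
            id=i,
            vertex_atoms=tuple(int(v) for v in simplices[i]),
            volume=float(volumes[i]),
            barycenter=barycenters[i],
        )
        for i in range(simplices.shape[0])
    ]

    # faces: canonical sorted vertex triple -> incident cells
    incidence: dict[tuple[int, int, int], list[int]] = {}
    for tid, simplex in enumerate(simplices):
        s = [int(v) for v in simplex]
        for skip in range(4):
            triple = tuple(s[j] for j in range(4) if j != skip)
            incidence.setdefault(triple, []).append(tid)

    faces: list[Face] = []
    face_of_triple: dict[tuple[int, int, int], int] = {}
    faces_of_tetra: dict[int, list[int]] = {t.id: [] for t in tetrahedra}
    hull_face_ids: set[int] = set()
    for fid, triple in enumerate(sorted(incidence)):
        cells = incidence[triple]
        if len(cells) == 1:
            pair = (cells[0], EXTERIOR)
        elif len(cells) == 2:
            pair = (min(cells), max(cells))
        else:  # pragma: no cover - impossible in a valid triangulation
            raise RuntimeError(f"face {triple} incident to {len(cells)} cells")
        area = face_area(points[triple[0]], points[triple[1]], points[triple[2]])
        face = Face(id=fid, vertex_atoms=triple, cells=pair, area=area)
        faces.append(face)
        face_of_triple[triple] = fid
        for tid in cells:
            faces_of_tetra[tid].append(fid)
        if pair[1] == EXTERIOR:
            hull_face_ids.add(fid)

    return Tessellation(
        atoms=atoms,
        points=points,
        radii=radii,
        tetrahedra=tetrahedra,
        faces=faces,
        hull_face_ids=hull_face_ids,
        face_of_triple=face_of_triple,
        faces_of_tetra=faces_of_tetra,
        jitter_applied=jitter_applied,
    )
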