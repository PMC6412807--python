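"""Exporting channels and paths as molecular files for any viewer.

Two modes, both plain PDB text:

* facial-graph mode: every tetrahedron becomes a virtual atom at the
  barycenter of its four vertex atoms, and every passable shared face
  becomes a pseudo-bond (CONECT) between the two virtual atoms;
* boundary mode: the region's real protein atoms with the edges of its
  closed (impassable) boundary faces written as pseudo-bonds.  These
  bonds come from the triangulation and are in general not chemical
  bonds.
"""

from __future__ import annotations

import warnings
from typing import Iterable

from .structure_io import _pdb_atom_line
from .tessellation import EXTERIOR, Tessellation

__all__ = ["export_facial_graph", "export_boundary", "export_filename"]

_MAX_SERIAL = 99999


def export_filename(structure_id: str, mode: str, cv: float) -> str:
    return f"{structure_id}_{mode}_{cv:g}.pdb"


def _conect_lines(bonds: dict[int, set[int]]) -> list[str]:
    lines = []
    for serial in sorted(bonds):
        partners = sorted(bonds[serial])
        for i in range(0, len(partners), 4):
            chunk = partners[i:i + 4]
            lines.append("CONECT" + f"{serial:>5d}" + "".join(f"{p:>5d}" for p in chunk) + "\n")
    return lines


def export_facial_graph(
    tess: Tessellation,
    cv: float,
    cells: Iterable[int] | None = None,
) -> str:
    """PDB text with one pseudo-atom per cell and bonds for passable doors.

    Pseudo-atoms (element C, residue TET, chain Z) sit at the cell
    barycenters, numbered deterministically by ascending tetra id; a
    CONECT pair is written for every shared face with CVmax >= cv whose
    both cells are included.
    """
    included = sorted(tess.region_cells() if cells is None else set(cells))
    if len(included) > _MAX_SERIAL:
        warnings.warn(
            f"{len(included)} pseudo-atoms exceed PDB serial space; "
            "writing MODEL blocks and dropping cross-model bonds",
            stacklevel=2,
        )
    serial_of = {tid: i + 1 for i, tid in enumerate(included)}
    model_of = {tid: (s - 1) // _MAX_SERIAL for tid, s in serial_of.items()}
    included_set = set(included)

    bonds: dict[int, set[int]] = {}
    for face in tess.faces:
        c1, c2 = face.cells
        if c2 == EXTERIOR or c1 not in included_set or c2 not in included_set:
            continue
        if face.cvmax < cv:
            continue
        if model_of[c1] != model_of[c2]:
            continue
        s1, s2 = serial_of[c1], serial_of[c2]
        bonds.setdefault(s1 % _MAX_SERIAL or _MAX_SERIAL, set()).add(s2 % _MAX_SERIAL or _MAX_SERIAL)

    n_models = (max(model_of.values()) + 1) if model_of else 1
    lines: list[str] = []
    for m in range(n_models):
        if n_models > 1:
            lines.append(f"MODEL     {m + 1:>4d}\n")
        for tid in included:
            if model_of[tid] != m:
                continue
            s = serial_of[tid] % _MAX_SERIAL or _MAX_SERIAL
            b = tess.tetrahedra[tid].barycenter
            lines.append(
                f"HETATM{s:>5d}  C   TET Z{(tid % 9999) + 1:>4d}    "
                f"{b[0]:8.3f}{b[1]:8.3f}{b[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"           C\n"
            )
        if n_models > 1:
            lines.append("ENDMDL\n")
    lines.extend(_conect_lines(bonds))
    lines.append("END\n")
    return "".join(lines)


def export_boundary(
    cells: Iterable[int],
    tess: Tessellation,
    cv: float,
) -> str:
    """PDB text of the region's atoms with its closed-face edges as bonds.

    Every edge of every boundary face (CVmax < cv, incident to the
    region) is written once as an undirected CONECT pair between the
    original protein atoms.
    """
    cell_set = set(cells)
    boundary_faces = []
    seen = set()
    for c in cell_set:
        for fid in tess.faces_of_tetra[c]:
            if fid in seen:
                continue
            seen.add(fid)
            if tess.faces[fid].cvmax < cv:
                boundary_faces.append(tess.faces[fid])

    atom_ids: set[int] = set()
    for c in cell_set:
        atom_ids.update(tess.tetrahedra[c].vertex_atoms)

    edges: set[tuple[int, int]] = set()
    for face in boundary_faces:
        i, j, k = face.vertex_atoms
        for a, b in ((i, j), (j, k), (i, k)):
            edges.add((min(a, b), max(a, b)))

    lines = []
    for i in sorted(atom_ids):
        a = tess.atoms[i]
        record = "ATOM" if a.category.value == "protein" else "HETATM"
        lines.append(_pdb_atom_line(a, record))
    bonds: dict[int, set[int]] = {}
    for a, b in edges:
        sa = tess.atoms[a].serial % 100000
        sb = tess.atoms[b].serial % 100000
        bonds.setdefault(sa, set()).add(sb)
    lines.extend(_conect_lines(bonds))
    lines.append("END\n")
    return "".join(lines)
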