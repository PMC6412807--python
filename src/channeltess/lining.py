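"""Lining atoms, residues and egress secondary structures of a region.

The atoms at the vertices of a channel's cells are its lining; grouped
by residue they give the channel-lining residue report, and the
secondary-structure elements containing the residues of the
hull-adjacent (mouth) cells annotate where the channel emerges.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple

from .pathfinding import Trajectory
from .structure_io import AtomCategory, SecondaryElement, StructureModel
from .tessellation import Tessellation

__all__ = ["Residue", "lining_atoms", "lining_residues", "egress_elements"]


class Residue(NamedTuple):
    chain_id: str
    number: int
    name: str

    def __str__(self) -> str:
        return f"{self.name}{self.number}({self.chain_id})"


def lining_atoms(cells: Iterable[int], tess: Tessellation) -> set[int]:
    """Union of the vertex atom indices of the given cells."""
    out: set[int] = set()
    for c in cells:
        out.update(tess.tetrahedra[c].vertex_atoms)
    return out


def lining_residues(
    cells: Iterable[int],
    tess: Tessellation,
) -> tuple[list[Residue], list[Residue]]:
    """Unique residues lining the cells, sorted by chain then number.

    Returns ``(protein_residues, cofactor_residues)`` — the heme (or
    other cofactor) is listed separately from the amino acids.
    """
    protein: set[Residue] = set()
    cofactor: set[Residue] = set()
    for i in lining_atoms(cells, tess):
        a = tess.atoms[i]
        res = Residue(a.chain_id, a.residue_number, a.residue_name)
        if a.category == AtomCategory.COFACTOR:
            cofactor.add(res)
        else:
            protein.add(res)
    key = lambda r: (r.chain_id, r.number)
    return sorted(protein, key=key), sorted(cofactor, key=key)


def _mouth_cells(traj: Trajectory, tess: Tessellation) -> set[int]:
    hull_cells = {tess.faces[fid].cells[0] for fid in tess.hull_face_ids}
    return set(traj.cells) & hull_cells


def egress_elements(
    traj: Trajectory,
    model: StructureModel,
    tess: Tessellation,
) -> list[SecondaryElement]:
    """Secondary-structure elements at which the trajectory emerges.

    Residues lining the hull-adjacent cells of the trajectory are looked
    up in the model's HELIX/SHEET elements; contiguous stretches of
    unmatched residues are reported as loop segments.
    """
    mouths = _mouth_cells(traj, tess)
    if not mouths:
        raise ValueError("trajectory does not reach the exterior")
    residues, _ = lining_residues(mouths, tess)

    matched: list[SecondaryElement] = []
    unmatched: list[Residue] = []
    for res in residues:
        hits = [el for el in model.elements if el.contains(res.chain_id, res.number)]
        for el in hits:
            if el not in matched:
                matched.append(el)
        if not hits:
            unmatched.append(res)

    # merge contiguous unmatched residues into loop segments
    loops: list[SecondaryElement] = []
    for res in unmatched:
        if (
            loops
            and loops[-1].chain_id == res.chain_id
            and res.number <= loops[-1].last_residue + 1
        ):
            loops[-1].last_residue = max(loops[-1].last_residue, res.number)
        else:
            loops.append(SecondaryElement(
                kind="loop",
                label=f"loop{len(loops) + 1}",
                chain_id=res.chain_id,
                first_residue=res.number,
                last_residue=res.number,
            ))
    return matched + loops
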