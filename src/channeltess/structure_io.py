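"""Reading and writing protein structures for channel analysis.

Parses PDB files into a light-weight atom model, classifies atoms as
protein / cofactor / ligand / water, assigns van der Waals radii, and
resolves the target atom that marks the buried active site (by default
the iron of the heme group).

Only heavy atoms are kept: the tessellation that downstream modules build
is a partition of the convex hull of the *heavy* atoms, and hydrogens are
usually absent from crystal structures anyway.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomCategory",
    "AtomRecord",
    "SecondaryElement",
    "StructureModel",
    "TargetSpec",
    "parse_structure",
    "load_structure",
    "default_radii",
    "assign_radii",
    "select_atoms",
    "resolve_target",
    "write_pdb",
]

# Residue names recognised as the heme cofactor (protoporphyrin IX variants).
COFACTOR_RESIDUES = {"HEM", "HEC", "HEA", "HEB"}
WATER_RESIDUES = {"HOH", "WAT", "DOD"}


class AtomCategory(str, Enum):
    PROTEIN = "protein"
    COFACTOR = "cofactor"
    LIGAND = "ligand"
    WATER = "water"


@dataclass(slots=True)
class AtomRecord:
    """One heavy atom.  Coordinates and radii are in angstroms."""

    serial: int
    name: str
    element: str
    alt_loc: str
    residue_name: str
    chain_id: str
    residue_number: int
    insertion_code: str
    coords: np.ndarray
    vdw_radius: float = 0.0
    category: AtomCategory = AtomCategory.PROTEIN


@dataclass(slots=True)
class SecondaryElement:
    """A secondary-structure element (from HELIX/SHEET records, or a loop)."""

    kind: str  # "helix" | "sheet" | "loop"
    label: str
    chain_id: str
    first_residue: int
    last_residue: int

    def __post_init__(self) -> None:
        if self.first_residue > self.last_residue:
            raise ValueError("first_residue must be <= last_residue")

    def contains(self, chain_id: str, residue_number: int) -> bool:
        return (
            chain_id == self.chain_id
            and self.first_residue <= residue_number <= self.last_residue
        )


@dataclass(slots=True)
class StructureModel:
    """An ordered collection of heavy atoms plus secondary-structure metadata."""

    atoms: list[AtomRecord]
    id: str = ""
    elements: list[SecondaryElement] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)


@dataclass(slots=True)
class TargetSpec:
    """Where the buried active site is.

    mode "atom_name": value is ``(atom_name, residue_name)``, e.g. the
    default ``("FE", "HEM")`` — the heme iron.
    mode "serial": value is a PDB atom serial number.
    mode "coords": value is a literal 3-vector in angstroms.
    """

    mode: str = "atom_name"
    value: object = ("FE", "HEM")

    @classmethod
    def default(cls) -> "TargetSpec":
        return cls()


def _infer_element(atom_name: str) -> str:
    """Best-effort element from an atom name (two-letter symbols first)."""
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    two = stripped[:2].upper()
    if two in {"FE", "ZN", "MG", "MN", "CU", "NA", "CL", "BR", "CA", "NI",
               "CO", "SE", "CD", "HG", "SI"}:
        return two
    return stripped[0].upper()


def _categorize(residue_name: str, is_hetatm: bool) -> AtomCategory:
    if not is_hetatm:
        return AtomCategory.PROTEIN
    if residue_name in COFACTOR_RESIDUES:
        return AtomCategory.COFACTOR
    if residue_name in WATER_RESIDUES:
        return AtomCategory.WATER
    return AtomCategory.LIGAND


def parse_structure(pdb_text: str, structure_id: str = "", chain: str | None = None) -> StructureModel:
    """Parse PDB text into a :class:`StructureModel` of heavy atoms.

    Hydrogens are dropped.  Alternate locations are resolved by keeping
    the highest-occupancy conformer (ties broken by the alphabetically
    first altLoc, i.e. 'A').  Only one chain is analysed: ``chain`` if
    given, otherwise the first chain in the file; HETATM groups on that
    chain (heme, ligands, waters) are kept with their category.
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise ValueError("no model found in PDB input")
    model = st[0]
    chain_names = [ch.name for ch in model]
    if not chain_names:
        raise ValueError("no parsable atom records in PDB input")
    if chain is None:
        chain = chain_names[0]
    elif chain not in chain_names:
        raise ValueError(f"chain {chain!r} not in structure (has {chain_names})")

    # collect heavy atoms of the selected chain, resolving alt-locs
    best: dict[tuple, tuple] = {}
    order: list[tuple] = []
    for ch in model:
        if ch.name != chain:
            continue
        for res in ch:
            is_het = res.het_flag == "H"
            for atom in res:
                element = atom.element.name.upper()
                if not element or element == "X":
                    element = _infer_element(atom.name)
                    warnings.warn(
                        f"element missing for atom {atom.serial} {atom.name!r}; "
                        f"inferred {element!r}",
                        stacklevel=2,
                    )
                if element in ("H", "D"):
                    continue
                key = (ch.name, res.seqid.num, res.seqid.icode, res.name, atom.name)
                rec = AtomRecord(
                    serial=atom.serial,
                    name=atom.name,
                    element=element,
                    alt_loc=atom.altloc or "",
                    residue_name=res.name,
                    chain_id=ch.name,
                    residue_number=res.seqid.num,
                    insertion_code=res.seqid.icode.strip(),
                    coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    category=_categorize(res.name, is_het),
                )
                cand = (-atom.occ, atom.altloc or "A", rec)
                if key not in best:
                    best[key] = cand
                    order.append(key)
                elif cand[:2] < best[key][:2]:
                    best[key] = cand
    atoms = [best[k][2] for k in order]
    if not atoms:
        raise ValueError("no parsable heavy-atom records in PDB input")

    elements: list[SecondaryElement] = []
    for i, h in enumerate(st.helices):
        if h.start.chain_name != chain:
            continue
        elements.append(SecondaryElement(
            kind="helix",
            label=f"H{i + 1}",
            chain_id=h.start.chain_name,
            first_residue=h.start.res_id.seqid.num,
            last_residue=h.end.res_id.seqid.num,
        ))
    for sheet in st.sheets:
        for strand in sheet.strands:
            if strand.start.chain_name != chain:
                continue
            elements.append(SecondaryElement(
                kind="sheet",
                label=sheet.name,
                chain_id=strand.start.chain_name,
                first_residue=strand.start.res_id.seqid.num,
                last_residue=strand.end.res_id.seqid.num,
            ))
    return StructureModel(atoms=atoms, id=structure_id or st.name or "", elements=elements)


def load_structure(path: str | Path, chain: str | None = None) -> StructureModel:
    path = Path(path)
    return parse_structure(path.read_text(), structure_id=path.stem, chain=chain)


def default_radii() -> tuple[dict[str, float], float]:
    """The packaged element → vdW-radius table and its default radius (Å)."""
    with resources.files("channeltess").joinpath("data/vdw_radii.json").open() as fh:
        data = json.load(fh)
    return {k.upper(): float(v) for k, v in data["radii"].items()}, float(data["default"])


def assign_radii(
    model: StructureModel,
    table: dict[str, float] | None = None,
    default: float | None = None,
) -> StructureModel:
    """Return a copy of ``model`` with van der Waals radii filled in.

    Unknown elements get the configured default radius, with a warning.
    """
    pkg_table, pkg_default = default_radii()
    if table is None:
        table = pkg_table
    else:
        table = {k.upper(): float(v) for k, v in table.items()}
    if default is None:
        default = pkg_default
    out = []
    for a in model.atoms:
        r = table.get(a.element.upper())
        if r is None:
            warnings.warn(
                f"no vdW radius for element {a.element!r}; using default {default} A",
                stacklevel=2,
            )
            r = default
        out.append(replace(a, coords=a.coords.copy(), vdw_radius=r))
    return StructureModel(atoms=out, id=model.id, elements=list(model.elements))


def select_atoms(
    model: StructureModel,
    include: Iterable[AtomCategory | str] = (AtomCategory.PROTEIN, AtomCategory.COFACTOR),
) -> list[AtomRecord]:
    """Atoms whose category is in ``include``, in file order.

    The default — protein plus cofactor, no waters, no co-crystallised
    ligand — is the point set whose voids the ligand is meant to travel
    through.
    """
    cats = {AtomCategory(c) for c in include}
    if not cats:
        raise ValueError("include set must be nonempty")
    selected = [a for a in model.atoms if a.category in cats]
    if not selected:
        raise ValueError(f"no atoms in categories {sorted(c.value for c in cats)}")
    return selected


def resolve_target(
    atoms: Sequence[AtomRecord] | StructureModel,
    spec: TargetSpec | None = None,
) -> int | np.ndarray:
    """Resolve a :class:`TargetSpec` to a unique atom index or a literal point.

    Returns the index into ``atoms`` (the tessellation point set) for the
    atom-based modes, or the 3-vector for mode "coords".
    """
    if isinstance(atoms, StructureModel):
        atoms = atoms.atoms
    if spec is None:
        spec = TargetSpec.default()
    if spec.mode == "coords":
        return np.asarray(spec.value, dtype=float).reshape(3)
    if spec.mode == "atom_name":
        name, resname = spec.value
        hits = [i for i, a in enumerate(atoms)
                if a.name.strip() == name and a.residue_name == resname]
    elif spec.mode == "serial":
        hits = [i for i, a in enumerate(atoms) if a.serial == int(spec.value)]
    else:
        raise ValueError(f"unknown target mode {spec.mode!r}")
    if len(hits) == 1:
        return hits[0]
    if not hits:
        raise ValueError(f"target {spec.mode}={spec.value!r} matches no atom")
    desc = ", ".join(
        f"{atoms[i].chain_id}/{atoms[i].residue_name}{atoms[i].residue_number}"
        f":{atoms[i].name}(serial {atoms[i].serial})" for i in hits
    )
    raise ValueError(f"target {spec.mode}={spec.value!r} is ambiguous: {desc}")


def _pdb_atom_line(a: AtomRecord, record: str) -> str:
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    return (
        f"{record:<6s}{a.serial % 100000:>5d} {name:<4.4s}{a.alt_loc[:1] or ' ':1s}"
        f"{a.residue_name:>3.3s} {a.chain_id[:1] or 'A':1s}{a.residue_number % 10000:>4d}"
        f"{a.insertion_code[:1] or ' ':1s}   "
        f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
        f"{1.0:6.2f}{0.0:6.2f}          {a.element:>2.2s}\n"
    )


def write_pdb(
    atoms: Sequence[AtomRecord],
    elements: Sequence[SecondaryElement] = (),
    remarks: Sequence[str] = (),
) -> str:
    """Serialise atoms (and optional HELIX/SHEET metadata) as PDB text."""
    lines: list[str] = []
    for r in remarks:
        lines.append(f"REMARK 999 {r}\n")
    n_helix = 0
    n_sheet = 0
    for el in elements:
        if el.kind == "helix":
            n_helix += 1
            lines.append(
                f"HELIX  {n_helix:>3d} {el.label[:3]:>3.3s} ALA {el.chain_id:1s} "
                f"{el.first_residue:>4d}  ALA {el.chain_id:1s} {el.last_residue:>4d}  1"
                f"{'':30s}{el.last_residue - el.first_residue + 1:>6d}\n"
            )
        elif el.kind == "sheet":
            n_sheet += 1
            lines.append(
                f"SHEET  {n_sheet:>3d} {el.label[:3]:>3.3s} 1 ALA {el.chain_id:1s}"
                f"{el.first_residue:>4d}  ALA {el.chain_id:1s}{el.last_residue:>4d}  0\n"
            )
    for a in atoms:
        record = "ATOM" if a.category == AtomCategory.PROTEIN else "HETATM"
        lines.append(_pdb_atom_line(a, record))
    lines.append("END\n")
    return "".join(lines)
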