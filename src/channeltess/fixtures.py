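"""Synthetic toy structures with analytically known channels.

A "shell pore" is a quasi-uniform spherical shell of atoms with one (or
two) circular gaps and a single buried target atom at the centre — a
minimal stand-in for a protein with a buried active site and one (or
two) access channels.  The gap of chord width w, pierced in a shell of
atoms of radius r, admits a disc of diameter approximately w - 2r, so
the whole pipeline can be checked against ground truth: CVlim should
recover the effective aperture, a second narrower pore should make a
second channel appear at lower CV, and paths through distinct pores
should cluster into distinct trajectories.

In the two-pore fixture an equatorial wall of atoms partitions the
interior cavity (leaving only sub-atomic clearances around the target),
so the two pores lead to the buried target through cell-disjoint voids:
without it a hollow shell is one connected cavity and the narrower pore
would never register as a separate channel component.

Atom placement uses a seeded Fibonacci spiral plus Gaussian jitter
(default 0.1 Å — also what keeps the backend triangulation away from the
exactly-cospherical degenerate case); the same seed reproduces the same
coordinates bit for bit.  The default shell density (800 atoms on a
10 Å sphere, ~1.25 Å spacing) keeps the CVlim discretisation error of
the pore ground truth well below the 0.5 Å fidelity the fixtures claim.
"""

from __future__ import annotations

import numpy as np

from .structure_io import (
    AtomCategory,
    AtomRecord,
    SecondaryElement,
    StructureModel,
    write_pdb,
)

__all__ = ["make_shell_pore", "make_two_pore", "fixture_pdb"]

DEFAULT_JITTER = 0.1


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n)
    z = 1.0 - 2.0 * (k + 0.5) / n  # decreasing from north to south pole
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(1.0 - z ** 2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _check_params(shell_radius, atom_radius, n_atoms, apertures, jitter):
    if n_atoms < 100:
        raise ValueError("n_atoms must be at least 100")
    if atom_radius <= 0 or shell_radius <= 0:
        raise ValueError("radii must be positive")
    for w in apertures:
        if w < 0 or w >= 2 * shell_radius:
            raise ValueError(f"aperture width {w} incompatible with shell radius")
    # shell must clear the central target atom and not fold onto itself
    if shell_radius < 3 * atom_radius or jitter > 0.25 * shell_radius:
        raise ValueError("parameters produce a self-intersecting shell")


def _build(
    shell_radius: float,
    atom_radius: float,
    n_atoms: int,
    apertures: tuple[float, ...],
    seed: int,
    jitter: float,
    structure_id: str,
) -> StructureModel:
    _check_params(shell_radius, atom_radius, n_atoms, apertures, jitter)
    pts = _fibonacci_sphere(n_atoms)
    keep = np.ones(n_atoms, dtype=bool)
    spacing = np.sqrt(4 * np.pi * shell_radius ** 2 / n_atoms)
    # Each pore is a polar cap cut out of the shell, "doored" by three
    # marker atoms on a circle of diameter aperture_width: the convex
    # hull caps the hole with the marker triangle, whose largest clear
    # disc has diameter aperture_width - 2*atom_radius exactly (the
    # analytic ground truth).  The cap is cut one atom spacing beyond
    # the marker circle so every other door around the rim stays closed.
    poles = [np.array([0.0, 0.0, 1.0]), np.array([0.0, 0.0, -1.0])]
    markers = []
    for p_idx, (w, pole) in enumerate(zip(apertures, poles)):
        if w <= 0:
            continue
        rho = w / 2.0
        cut = min(rho + spacing, 0.95 * shell_radius)
        sin_cut = cut / shell_radius
        cos_cut = np.sqrt(1.0 - sin_cut ** 2)
        keep &= (pts @ pole) < cos_cut
        z_m = pole[2] * np.sqrt(shell_radius ** 2 - rho ** 2)
        for j in range(3):
            phi = 2 * np.pi * j / 3 + p_idx * np.pi / 3
            markers.append([rho * np.cos(phi), rho * np.sin(phi), z_m])
    pts = pts[keep] * shell_radius
    n_shell = len(pts)

    wall_pts = np.zeros((0, 3))
    if len(apertures) > 1:
        # equatorial partition: concentric rings from just outside the
        # target atom to the shell, splitting the cavity in two
        ring_step = 0.9 * spacing
        # innermost ring touches the central target sphere, so the two
        # half-cavities stay sealed from each other while each keeps
        # wide-doored cells incident to the target vertex
        r0 = 2.0 + atom_radius
        rows = []
        r = r0
        while r < shell_radius - 0.3 * ring_step:
            m = max(6, int(np.ceil(2 * np.pi * r / ring_step)))
            ang = 2 * np.pi * np.arange(m) / m
            rows.append(np.column_stack([r * np.cos(ang), r * np.sin(ang), np.zeros(m)]))
            r += ring_step
        if rows:
            wall_pts = np.vstack(rows)

    rng = np.random.default_rng(seed)
    pts = np.vstack([pts, wall_pts] + ([np.array(markers)] if markers else []))
    pts = pts + rng.normal(scale=jitter, size=pts.shape)
    n_before_markers = len(pts) - len(markers)

    atoms = [
        AtomRecord(
            serial=i + 1,
            name="CA",
            element="C",
            alt_loc="",
            residue_name="ALA",
            chain_id="A",
            residue_number=i + 1,
            insertion_code="",
            coords=pts[i],
            vdw_radius=atom_radius,
            category=AtomCategory.PROTEIN,
        )
        for i in range(len(pts))
    ]
    n_total = len(atoms)
    atoms.append(AtomRecord(
        serial=n_total + 1,
        name="FE",
        element="FE",
        alt_loc="",
        residue_name="HEM",
        chain_id="A",
        residue_number=n_total + 1,
        insertion_code="",
        coords=np.zeros(3),
        vdw_radius=2.0,
        category=AtomCategory.COFACTOR,
    ))

    # annotate each pore's three door atoms as a labelled mouth "helix"
    # (they are the last atoms, appended pore by pore)
    elements = []
    res0 = n_before_markers + 1
    m_idx = 0
    for p_idx, w in enumerate(apertures):
        if w <= 0:
            continue
        elements.append(SecondaryElement(
            kind="helix", label=f"MT{p_idx + 1}", chain_id="A",
            first_residue=res0 + m_idx, last_residue=res0 + m_idx + 2,
        ))
        m_idx += 3
    return StructureModel(atoms=atoms, id=structure_id, elements=elements)


def make_shell_pore(
    shell_radius: float = 10.0,
    atom_radius: float = 1.7,
    n_atoms: int = 800,
    aperture_width: float = 8.0,
    seed: int = 0,
    jitter: float = DEFAULT_JITTER,
) -> StructureModel:
    """Atom shell with one pore and a buried central target atom.

    The expected limiting thickness is ``aperture_width - 2 * atom_radius``
    up to the shell discretisation.  ``aperture_width = 0`` gives a closed
    shell with no channel.  The default atom radius matches the carbon
    entry of the packaged radii table so a PDB round trip preserves the
    ground truth.
    """
    return _build(
        shell_radius, atom_radius, n_atoms, (aperture_width,), seed, jitter,
        structure_id=f"shellpore_w{aperture_width:g}_s{seed}",
    )


def make_two_pore(
    shell_radius: float = 10.0,
    atom_radius: float = 1.7,
    n_atoms: int = 800,
    aperture1: float = 8.0,
    aperture2: float = 7.5,
    seed: int = 0,
    jitter: float = DEFAULT_JITTER,
) -> StructureModel:
    """Shell with two pores on opposite poles (widths ``aperture1``/``aperture2``).

    With ``aperture1 > aperture2`` the first access channel appears at
    about ``aperture1 - 2r`` and a second, cell-disjoint one near
    ``aperture2 - 2r``.  At a CV between the sliver-door width of the
    wide pore (about ``0.87*aperture1 - 2r``) and the narrow pore's
    door width, each pore admits exactly one minimal cost path, so the
    default apertures are close together to keep that window open.
    """
    return _build(
        shell_radius, atom_radius, n_atoms, (aperture1, aperture2), seed, jitter,
        structure_id=f"twopore_w{aperture1:g}_{aperture2:g}_s{seed}",
    )


def fixture_pdb(model: StructureModel, seed: int | None = None, jitter: float = DEFAULT_JITTER) -> str:
    """Serialise a fixture as PDB text, recording generation parameters."""
    remarks = [f"synthetic fixture {model.id}"]
    if seed is not None:
        remarks.append(f"generator seed {seed}, jitter {jitter} A")
    return write_pdb(model.atoms, elements=model.elements, remarks=remarks)
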