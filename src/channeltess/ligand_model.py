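"""Critical thickness of a ligand under the cylindrical model.

A ligand's critical value CV is the diameter of the thinnest infinite
cylinder enclosing all its atom spheres:

    CV = 2 * min_axis max_i ( dist_perp(atom_i, axis) + r_i ),

minimised over axis direction and position.  The direction search uses a
Fibonacci-sphere grid followed by local refinement; for each direction
the optimal axis position is the centre of the smallest enclosing circle
of the projected atom centres with their radii added.

The cylinder convention is a package-level reconstruction (the
literature convention is not fully printed anywhere we could follow),
so the rest of the pipeline always accepts an explicit CV instead.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from .structure_io import AtomCategory, AtomRecord, StructureModel

__all__ = [
    "ligand_thickness",
    "ligand_from_model",
    "enclosing_sphere_diameter",
]


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """n quasi-uniform directions on the upper hemisphere (axes are unsigned)."""
    k = np.arange(n)
    z = (k + 0.5) / n  # upper hemisphere only
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(1.0 - z ** 2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _enclosing_radius(points: np.ndarray, radii: np.ndarray, polish: bool) -> float:
    """min over c of max_i (||x_i - c|| + r_i), any dimension.

    Frank-Wolfe style iteration toward the farthest sphere, optionally
    polished with a simplex search (the objective is convex but
    nonsmooth).
    """
    c = points.mean(axis=0)

    def g(c):
        return float((np.linalg.norm(points - c, axis=1) + radii).max())

    for k in range(80):
        i = int(np.argmax(np.linalg.norm(points - c, axis=1) + radii))
        c = c + (points[i] - c) / (k + 2.0)
    if polish:
        res = minimize(g, c, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 400})
        return float(res.fun)
    return g(c)


def _width(u: np.ndarray, coords: np.ndarray, radii: np.ndarray, polish: bool) -> float:
    """Diameter of the thinnest enclosing cylinder with axis direction u."""
    u = u / np.linalg.norm(u)
    # orthonormal basis of the plane perpendicular to u
    a = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    proj = coords @ np.column_stack([e1, e2])
    return 2.0 * _enclosing_radius(proj, radii, polish)


def _sph(theta: float, phi: float) -> np.ndarray:
    return np.array([
        np.sin(theta) * np.cos(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(theta),
    ])


def ligand_thickness(
    atoms: list[AtomRecord] | np.ndarray,
    radii: np.ndarray | None = None,
    n_directions: int = 500,
    refine: bool = True,
    include_radii: bool = True,
) -> float:
    """Critical thickness CV (Å) of a set of atom spheres.

    ``atoms`` is either a list of radius-assigned :class:`AtomRecord` or
    a coordinate array with ``radii`` given separately.  With
    ``include_radii=False`` the cylinder encloses only the atom centres
    (the alternative centre-only convention).
    """
    if isinstance(atoms, np.ndarray):
        coords = np.asarray(atoms, dtype=float).reshape(-1, 3)
        radii = np.zeros(len(coords)) if radii is None else np.asarray(radii, float)
    else:
        if not atoms:
            raise ValueError("ligand has no atoms")
        coords = np.array([a.coords for a in atoms], dtype=float)
        radii = np.array([a.vdw_radius for a in atoms], dtype=float)
    if not include_radii:
        radii = np.zeros_like(radii)
    if len(coords) == 1:
        return float(2.0 * radii[0])

    dirs = _fibonacci_hemisphere(max(8, n_directions))
    widths = np.array([_width(u, coords, radii, polish=False) for u in dirs])
    order = np.argsort(widths)

    best = float(widths[order[0]])
    best_u = dirs[order[0]]
    # polish the most promising directions accurately
    for i in order[:5]:
        w = _width(dirs[i], coords, radii, polish=True)
        if w < best:
            best, best_u = w, dirs[i]

    if refine:
        theta0 = float(np.arccos(np.clip(best_u[2], -1.0, 1.0)))
        phi0 = float(np.arctan2(best_u[1], best_u[0]))
        res = minimize(
            lambda ang: _width(_sph(*ang), coords, radii, polish=True),
            np.array([theta0, phi0]),
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 200},
        )
        if res.fun < best:
            best = float(res.fun)
    return best


def ligand_from_model(model: StructureModel, resname: str) -> list[AtomRecord]:
    """Atoms of the first (in file order) ligand residue named ``resname``."""
    groups: dict[tuple, list[AtomRecord]] = {}
    order = []
    for a in model.atoms:
        if a.residue_name != resname:
            continue
        if a.category not in (AtomCategory.LIGAND, AtomCategory.COFACTOR):
            continue
        key = (a.chain_id, a.residue_number, a.insertion_code)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(a)
    if not order:
        raise ValueError(f"no ligand residue {resname!r} in structure {model.id!r}")
    return groups[order[0]]


def enclosing_sphere_diameter(coords: np.ndarray, radii: np.ndarray) -> float:
    """Diameter of the smallest sphere enclosing all atom spheres.

    An upper bound for the cylinder thickness (every enclosing sphere
    yields an enclosing cylinder of the same diameter).
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii, dtype=float)
    return 2.0 * _enclosing_radius(coords, radii, polish=True)
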