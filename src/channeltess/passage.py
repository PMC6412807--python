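"""Passability of triangular doors.

Each triangular face of the tessellation, with the van der Waals spheres
of its three vertex atoms, acts as a door.  A ligand is modelled by the
circular cross-section (diameter CV) of its cylindrical shape, so the
widest hypothetical ligand that fits through a door has diameter

    CVmax = 2 * max(0, max_{c in triangle} min_i (||c - p_i|| - r_i)),

the diameter of the largest disc centred inside the closed triangle and
clear of the three vertex spheres.  Only the three vertex atoms obstruct
their own door; occlusion by neighbouring atoms is expressed by the
adjacent doors they belong to.

The maximiser of the min-clearance is found exactly by enumerating the
finitely many candidate points where the Karush-Kuhn-Tucker conditions
can hold:

* the (weighted) Apollonius point equidistant in clearance from all three
  spheres, when it falls inside the triangle;
* on each triangle edge, the points where two clearances are equal;
* the triangle vertices.

A brute-force grid maximiser (`cvmax_oracle`) provides an independent
check: the clearance field is 1-Lipschitz, which makes coarse-to-fine
grid refinement with pruning sound.
"""

from __future__ import annotations

import numpy as np

from .tessellation import Tessellation

__all__ = ["face_cvmax", "annotate_cvmax", "cvmax_oracle"]

_EPS = 1e-9


def _to_plane(p1, p2, p3):
    """Orthonormal 2D coordinates of the triangle in its own plane."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    u = p2 - p1
    nu = np.linalg.norm(u)
    if nu < _EPS:
        return None
    e1 = u / nu
    w = p3 - p1
    w_perp = w - np.dot(w, e1) * e1
    nw = np.linalg.norm(w_perp)
    if nw < _EPS:
        return None
    e2 = w_perp / nw
    a = np.array([0.0, 0.0])
    b = np.array([nu, 0.0])
    c = np.array([np.dot(w, e1), nw])
    return a, b, c


def _clearance(q: np.ndarray, sites: np.ndarray, radii: np.ndarray) -> float:
    d = np.linalg.norm(sites - q, axis=1) - radii
    return float(d.min())


def _inside(q, a, b, c, tol=1e-7) -> bool:
    # barycentric test in 2D
    m = np.column_stack([b - a, c - a])
    det = np.linalg.det(m)
    if abs(det) < _EPS:
        return False
    lam = np.linalg.solve(m, q - a)
    l1, l2 = lam
    return l1 >= -tol and l2 >= -tol and (l1 + l2) <= 1 + tol


def _apollonius_candidates(sites, radii):
    """Points with equal clearance t to all three sites (2D), as (point, t)."""
    (x1, y1), (x2, y2), (x3, y3) = sites
    r1, r2, r3 = radii
    # (x-xi)^2 + (y-yi)^2 = (t+ri)^2 ; subtract pairs -> linear in (x, y, t)
    A = np.array([[2 * (x2 - x1), 2 * (y2 - y1)],
                  [2 * (x3 - x1), 2 * (y3 - y1)]])
    if abs(np.linalg.det(A)) < _EPS:
        return []
    c0 = np.array([
        (x2 ** 2 + y2 ** 2 - x1 ** 2 - y1 ** 2) + (r1 ** 2 - r2 ** 2),
        (x3 ** 2 + y3 ** 2 - x1 ** 2 - y1 ** 2) + (r1 ** 2 - r3 ** 2),
    ])
    c1 = np.array([2 * (r1 - r2), 2 * (r1 - r3)])
    u = np.linalg.solve(A, c0)   # point = u + v * t
    v = np.linalg.solve(A, c1)
    # ||u + v t - p1||^2 = (t + r1)^2  ->  quadratic in t
    w = u - np.array([x1, y1])
    qa = float(v @ v) - 1.0
    qb = 2.0 * float(w @ v) - 2.0 * r1
    qc = float(w @ w) - r1 ** 2
    out = []
    if abs(qa) < _EPS:
        if abs(qb) > _EPS:
            t = -qc / qb
            out.append((u + v * t, t))
    else:
        disc = qb ** 2 - 4 * qa * qc
        if disc >= 0:
            sq = np.sqrt(disc)
            for t in ((-qb + sq) / (2 * qa), (-qb - sq) / (2 * qa)):
                out.append((u + v * t, t))
    # keep only roots where all clearance distances are nonnegative
    return [(q, t) for q, t in out
            if all(t + r >= -1e-7 for r in radii)]


def _edge_equalization(q0, d, sites, radii, i, j):
    """s-values in [0,1] on segment q0 + s*d where clearances i and j match."""
    pi, pj = sites[i], sites[j]
    ri, rj = radii[i], radii[j]
    k = ri - rj
    wi = q0 - pi
    wj = q0 - pj
    dd = float(d @ d)
    if dd < _EPS:
        return []
    # fi(s)^2 - fj(s)^2 is linear in s
    l1 = 2.0 * float(d @ (wi - wj))
    l0 = float(wi @ wi - wj @ wj)
    roots = []
    if abs(k) < _EPS:
        if abs(l1) > _EPS:
            roots.append(-l0 / l1)
    else:
        # fj(s) = (L(s)/k - k) / 2 with L = l0 + l1 s ; square both sides
        a2 = (l1 / k) ** 2 / 4.0 - dd
        a1 = (l1 / k) * (l0 / k - k) / 2.0 - 2.0 * float(d @ wj)
        a0 = (l0 / k - k) ** 2 / 4.0 - float(wj @ wj)
        if abs(a2) < _EPS:
            if abs(a1) > _EPS:
                roots.append(-a0 / a1)
        else:
            disc = a1 ** 2 - 4 * a2 * a0
            if disc >= 0:
                sq = np.sqrt(disc)
                roots.extend([(-a1 + sq) / (2 * a2), (-a1 - sq) / (2 * a2)])
    good = []
    for s in roots:
        if -1e-9 <= s <= 1 + 1e-9:
            q = q0 + np.clip(s, 0.0, 1.0) * d
            fi = np.linalg.norm(q - pi) - ri
            fj = np.linalg.norm(q - pj) - rj
            if abs(fi - fj) < 1e-6 * (1 + abs(fi)):
                good.append(np.clip(s, 0.0, 1.0))
    return good


def face_cvmax(p1, p2, p3, r1: float, r2: float, r3: float) -> float:
    """CVmax of the door formed by three atoms (positions Å, vdW radii Å).

    Returns 0 for a degenerate (collinear) triangle or a fully obstructed
    door.
    """
    plane = _to_plane(p1, p2, p3)
    if plane is None:
        return 0.0
    a, b, c = plane
    sites = np.array([a, b, c])
    radii = np.array([r1, r2, r3], dtype=float)

    best = -np.inf
    # triangle vertices
    for q in (a, b, c):
        best = max(best, _clearance(q, sites, radii))
    # interior equal-clearance (Apollonius) points
    for q, _t in _apollonius_candidates(sites, radii):
        if _inside(q, a, b, c):
            best = max(best, _clearance(q, sites, radii))
    # edge-restricted two-clearance equalization points
    for q0, q1 in ((a, b), (b, c), (c, a)):
        d = q1 - q0
        for i in range(3):
            for j in range(i + 1, 3):
                for s in _edge_equalization(q0, d, sites, radii, i, j):
                    best = max(best, _clearance(q0 + s * d, sites, radii))
    return 2.0 * max(0.0, best)


def annotate_cvmax(tess: Tessellation) -> Tessellation:
    """Compute and store CVmax on every face (hull faces included)."""
    pts = tess.points
    rad = tess.radii
    for face in tess.faces:
        i, j, k = face.vertex_atoms
        face.cvmax = face_cvmax(pts[i], pts[j], pts[k], rad[i], rad[j], rad[k])
    return tess


def cvmax_oracle(p1, p2, p3, r1: float, r2: float, r3: float, step: float = 1e-3) -> float:
    """Brute-force CVmax by grid maximisation of the min-clearance field.

    Coarse-to-fine refinement over a barycentric grid; since the
    clearance field is 1-Lipschitz, pruning cells whose value is more
    than 2.5 grid pitches below the current best cannot discard the
    global maximiser.  The final grid pitch is <= ``step``, so the result
    is within O(step) of the true maximum.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    plane = _to_plane(p1, p2, p3)
    if plane is None:
        return 0.0
    a, b, c = plane
    sites = np.array([a, b, c])
    radii = np.array([r1, r2, r3], dtype=float)
    max_edge = max(np.linalg.norm(b - a), np.linalg.norm(c - b), np.linalg.norm(a - c))

    n = 16
    ij = np.array([(i, j) for i in range(n + 1) for j in range(n + 1 - i)], dtype=np.int64)
    best = -np.inf
    while True:
        q = a + np.outer(ij[:, 0] / n, b - a) + np.outer(ij[:, 1] / n, c - a)
        f = (np.linalg.norm(q[:, None, :] - sites[None, :, :], axis=2) - radii).min(axis=1)
        best = max(best, float(f.max()))
        pitch = 1.5 * max_edge / n
        if pitch <= step:
            break
        keep = ij[f >= best - 2.5 * pitch]
        # children at 4x resolution within one parent cell of each kept point
        offs = np.arange(-4, 5)
        da, db = np.meshgrid(offs, offs, indexing="ij")
        children = (keep[:, None, None, :] * 4
                    + np.stack([da, db], axis=-1)[None, :, :, :]).reshape(-1, 2)
        n *= 4
        children = children[(children[:, 0] >= 0) & (children[:, 1] >= 0)
                            & (children.sum(axis=1) <= n)]
        ij = np.unique(children, axis=0)
    return 2.0 * max(0.0, best)
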