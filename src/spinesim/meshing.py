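"""Tetrahedral meshing of implicitly defined (SDF) geometry.

The generator builds a structured background lattice of cubes, each
subdivided into six tetrahedra sharing the main diagonal (Kuhn /
Freudenthal subdivision, conforming across cubes), and clips it against
signed-distance functions by marching-tetrahedra decomposition:

* tets fully inside are kept, fully outside dropped,
* mixed tets are cut along the linear interpolant of the SDF into
  sub-tets; edge cut points are cached globally so neighbouring tets
  (and the two sides of an interface) share vertices exactly,
* quad faces arising in two-in/two-out cuts are triangulated by a
  diagonal chosen from global vertex indices only, which makes the
  decomposition conforming across tets and across the interface.

The interface between two clip passes therefore becomes an exactly
shared triangulated surface -- this is how the ER membrane separating
cytosol and ER lumen is produced.
"""

from __future__ import annotations

from typing import Callable, Dict, List, Tuple

import numpy as np

from .mesh import tet_signed_volumes

# six tets of the Kuhn subdivision of the unit cube: each is the chain
# 0 -> e_p1 -> e_p1+e_p2 -> (1,1,1) over a permutation (p1,p2,p3)
_PERMS = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]


def kuhn_lattice(bounds: np.ndarray, h: float) -> Tuple[np.ndarray, np.ndarray]:
    """Background lattice covering ``bounds`` (2x3 array) at spacing ``h``."""
    lo, hi = np.asarray(bounds, float)
    n = np.maximum(np.ceil((hi - lo) / h).astype(int), 1)
    axes = [np.linspace(lo[d], lo[d] + n[d] * h, n[d] + 1) for d in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    verts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    nx, ny, nz = n + 1

    def vid(i, j, k):
        return (i * ny + j) * nz + k

    I, J, K = np.meshgrid(np.arange(n[0]), np.arange(n[1]), np.arange(n[2]),
                          indexing="ij")
    I, J, K = I.ravel(), J.ravel(), K.ravel()
    corner = [I, J, K]
    tets = []
    for p in _PERMS:
        idx = [corner[0].copy(), corner[1].copy(), corner[2].copy()]
        chain = [vid(*idx)]
        for ax in p:
            idx[ax] = idx[ax] + 1
            chain.append(vid(*idx))
        tets.append(np.column_stack(chain))
    tets = np.vstack(tets)
    # orient positively
    vols = tet_signed_volumes(verts, tets)
    flip = vols < 0
    t = tets.copy()
    t[flip, 2], t[flip, 3] = tets[flip, 3], tets[flip, 2]
    return verts, t


class _VertexPool:
    """Growing vertex array with a shared edge-cut-point cache."""

    def __init__(self, verts: np.ndarray):
        self.verts: List[np.ndarray] = list(np.asarray(verts, float))
        self.cut_cache: Dict[Tuple[int, int], int] = {}

    def as_array(self) -> np.ndarray:
        return np.asarray(self.verts)

    def cut_point(self, i: int, j: int, phi_i: float, phi_j: float,
                  snap: float = 1e-4) -> int:
        key = (i, j) if i < j else (j, i)
        hit = self.cut_cache.get(key)
        if hit is not None:
            return hit
        t = phi_i / (phi_i - phi_j)
        if t < snap:
            idx = i
        elif t > 1 - snap:
            idx = j
        else:
            p = self.verts[i] + t * (np.asarray(self.verts[j]) - self.verts[i])
            self.verts.append(p)
            idx = len(self.verts) - 1
        self.cut_cache[key] = idx
        return idx


def _quad_diag_through_q0(q) -> bool:
    """Diagonal choice for quad (q0,q1,q2,q3): through q0-q2 or q1-q3.

    Depends only on the unordered vertex pairs, so both tets sharing the
    quad (and both sides of an interface) pick the same diagonal.
    """
    return min(q[0], q[2]) < min(q[1], q[3])


def _split_prism(b, t) -> List[Tuple[int, int, int, int]]:
    """Tetrahedralize prism (b0,b1,b2)/(t0,t1,t2) honouring the global
    diagonal rule on its three quad faces."""
    quads = [(b[i], b[(i + 1) % 3], t[(i + 1) % 3], t[i]) for i in range(3)]
    diag0 = [_quad_diag_through_q0(q) for q in quads]  # True: (b_i, t_{i+1})

    # apex fan: vertex whose two adjacent quads both have their diagonal
    # incident to it
    for i in range(3):
        # b_i belongs to quads Q_{i-1} (as q1) and Q_i (as q0)
        if diag0[i] and not diag0[(i - 1) % 3]:
            apex = b[i]
            far_quad = quads[(i + 1) % 3]
            tris = _quad_tris(far_quad)
            top = (t[0], t[1], t[2])
            return [(apex,) + top] + [(apex,) + tr for tr in tris]
        # t_i belongs to quads Q_{i-1} (as q2) and Q_i (as q3)
        if not diag0[i] and diag0[(i - 1) % 3]:
            apex = t[i]
            far_quad = quads[(i + 1) % 3]
            tris = _quad_tris(far_quad)
            bot = (b[0], b[1], b[2])
            return [(apex,) + bot] + [(apex,) + tr for tr in tris]
    # cyclic diagonal pattern: no 3-tet split exists -> centroid split
    return None


def _quad_tris(q) -> List[Tuple[int, int, int]]:
    if _quad_diag_through_q0(q):
        return [(q[0], q[1], q[2]), (q[0], q[2], q[3])]
    return [(q[1], q[2], q[3]), (q[1], q[3], q[0])]


def clip_tets(pool: _VertexPool, tets: np.ndarray, phi: np.ndarray,
              keep_negative: bool = True) -> np.ndarray:
    """Sub-tets of ``tets`` covering the region where phi < 0 (or > 0).

    ``phi`` holds SDF values for every vertex currently in the pool that
    appears in ``tets``; exact zeros must be nudged by the caller so the
    two complementary calls partition the background exactly.
    """
    phi = np.asarray(phi, float)
    s = phi if keep_negative else -phi
    inside = s < 0

    tet_in = inside[tets]
    count = tet_in.sum(axis=1)
    keep_whole = tets[count == 4]
    mixed = tets[(count > 0) & (count < 4)]
    mixed_in = tet_in[(count > 0) & (count < 4)]

    out: List[Tuple[int, int, int, int]] = []
    centroid_extra: List[Tuple[np.ndarray, List[Tuple[int, int, int]]]] = []
    for tet, ins in zip(mixed, mixed_in):
        iv = [int(v) for v, f in zip(tet, ins) if f]
        ov = [int(v) for v, f in zip(tet, ins) if not f]
        cut = lambda a, b: pool.cut_point(a, b, s[a] if a < len(s) else 0.0,
                                          s[b] if b < len(s) else 0.0)
        if len(iv) == 1:
            a = iv[0]
            ps = [cut(a, o) for o in ov]
            out.append((a, ps[0], ps[1], ps[2]))
        elif len(iv) == 3:
            d = ov[0]
            pd = [cut(v, d) for v in iv]
            pieces = _split_prism(tuple(iv), tuple(pd))
            if pieces is None:
                pieces = _centroid_split_prism(pool, tuple(iv), tuple(pd))
            out.extend(pieces)
        else:  # two inside
            a, b = iv
            c, d = ov
            pac, pad = cut(a, c), cut(a, d)
            pbc, pbd = cut(b, c), cut(b, d)
            pieces = _split_prism((a, pac, pad), (b, pbc, pbd))
            if pieces is None:
                pieces = _centroid_split_prism(pool, (a, pac, pad), (b, pbc, pbd))
            out.extend(pieces)

    all_tets = [keep_whole] if len(keep_whole) else []
    if out:
        all_tets.append(np.asarray(out, dtype=np.int64))
    if not all_tets:
        return np.empty((0, 4), dtype=np.int64)
    result = np.vstack(all_tets)

    verts = pool.as_array()
    vols = tet_signed_volumes(verts, result)
    swap = vols < 0
    r = result.copy()
    r[swap, 2], r[swap, 3] = result[swap, 3], result[swap, 2]
    good = np.abs(vols) > 1e-18
    return r[good]


def _centroid_split_prism(pool: _VertexPool, b, t):
    """Fallback for the cyclic-diagonal prism: fan from its centroid."""
    verts = pool.as_array()
    c = verts[list(b) + list(t)].mean(axis=0)
    pool.verts.append(c)
    ci = len(pool.verts) - 1
    pieces = [(ci, b[0], b[1], b[2]), (ci, t[0], t[2], t[1])]
    for i in range(3):
        q = (b[i], b[(i + 1) % 3], t[(i + 1) % 3], t[i])
        for tr in _quad_tris(q):
            pieces.append((ci,) + tr)
    return pieces


def mesh_two_phase(bounds, h: float,
                   phi_outer: Callable[[np.ndarray], np.ndarray],
                   phi_inner: Callable[[np.ndarray], np.ndarray] | None = None,
                   ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mesh {phi_outer<0}, partitioned into inner (phi_inner<0) and rest.

    Returns ``(vertices, tets, phase)`` with phase 1 for the outer phase
    (phi_inner > 0 or absent) and 2 for the inner phase.
    """
    bg_verts, bg_tets = kuhn_lattice(bounds, h)
    pool = _VertexPool(bg_verts)
    phi = _nudged(phi_outer(bg_verts))
    domain = clip_tets(pool, bg_tets, phi, keep_negative=True)

    if phi_inner is None:
        verts = pool.as_array()
        verts, tets = _compact(verts, domain)
        return verts, tets, np.ones(len(tets), dtype=np.int8)

    verts_now = pool.as_array()
    phi2 = _nudged(phi_inner(verts_now))
    # shared cut cache is reset between passes: pass-two cuts live on new
    # edges; the cache inside the pool still guarantees both phases agree
    pool.cut_cache = {}
    inner = clip_tets(pool, domain, phi2, keep_negative=True)
    # pad phi2 for vertices created by the inner clip (unused afterwards)
    outer = clip_tets(pool, domain, phi2, keep_negative=False)

    tets = np.vstack([outer, inner])
    phase = np.concatenate([
        np.ones(len(outer), dtype=np.int8),
        np.full(len(inner), 2, dtype=np.int8),
    ])
    verts, tets, order = _compact_keepphase(pool.as_array(), tets)
    return verts, tets, phase


def _nudged(phi: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    phi = np.asarray(phi, float).copy()
    phi[phi == 0.0] = eps
    return phi


def _compact(verts, tets):
    used, inv = np.unique(tets, return_inverse=True)
    return verts[used], inv.reshape(tets.shape)


def _compact_keepphase(verts, tets):
    used, inv = np.unique(tets, return_inverse=True)
    return verts[used], inv.reshape(tets.shape), used


# ----------------------------------------------------------------------
# signed-distance primitives (exact near their surfaces, which is all the
# linear cut interpolation needs)

def sdf_sphere(p: np.ndarray, center, r: float) -> np.ndarray:
    return np.linalg.norm(p - np.asarray(center), axis=1) - r


def sdf_cylinder_x(p: np.ndarray, y0: float, z0: float, r: float,
                   x_half: float, x_center: float = 0.0) -> np.ndarray:
    """Capped cylinder along x with axis through (y0, z0)."""
    d_rad = np.hypot(p[:, 1] - y0, p[:, 2] - z0) - r
    d_ax = np.abs(p[:, 0] - x_center) - x_half
    return _capped(d_rad, d_ax)


def sdf_cylinder_z(p: np.ndarray, x0: float, y0: float, r: float,
                   z_lo: float, z_hi: float) -> np.ndarray:
    d_rad = np.hypot(p[:, 0] - x0, p[:, 1] - y0) - r
    mid, half = 0.5 * (z_lo + z_hi), 0.5 * (z_hi - z_lo)
    d_ax = np.abs(p[:, 2] - mid) - half
    return _capped(d_rad, d_ax)


def sdf_capsule_z(p: np.ndarray, x0: float, y0: float, z_lo: float,
                  z_hi: float, r: float) -> np.ndarray:
    """Capsule (cylinder with spherical caps) along z."""
    zc = np.clip(p[:, 2], z_lo, z_hi)
    return np.sqrt((p[:, 0] - x0) ** 2 + (p[:, 1] - y0) ** 2
                   + (p[:, 2] - zc) ** 2) - r


def _capped(d_rad: np.ndarray, d_ax: np.ndarray) -> np.ndarray:
    inside = np.maximum(d_rad, d_ax)
    a = np.maximum(d_rad, 0.0)
    b = np.maximum(d_ax, 0.0)
    outside = np.sqrt(a * a + b * b)
    return np.where(inside < 0, inside, outside)


def sdf_union(*phis) -> np.ndarray:
    out = phis[0]
    for q in phis[1:]:
        out = np.minimum(out, q)
    return out
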