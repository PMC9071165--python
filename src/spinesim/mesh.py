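"""Labeled tetrahedral meshes and their quality/morphometric reports.

A :class:`TetMesh` carries two volume subdomains -- cytosol and ER lumen
-- plus derived boundary-triangle labels (plasma membrane, ER membrane,
PSD, closed ends of the dendritic segment) and per-cytosol-tet measuring
zones (head / neck / dendrite / far dendrite).  All coordinates are µm.

Conventions: the dendrite axis is x, the spine axis is z, and the spine
base (neck insertion into the dendritic surface) sits at the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

# volume subset codes
CYTOSOL = 1
ER_LUMEN = 2

# surface subset codes
PM = 1
ERM = 2
PSD = 3
CLOSED_END = 4

# zone codes (cytosol tets; 0 for ER tets)
HEAD = 1
NECK = 2
DENDRITE = 3          # dendritic measuring zone (±0.5 µm of the insertion)
DENDRITE_FAR = 4

SURFACE_NAMES = {PM: "pm", ERM: "erm", PSD: "psd", CLOSED_END: "closed_end"}
VOLUME_NAMES = {CYTOSOL: "cytosol", ER_LUMEN: "er_lumen"}
ZONE_NAMES = {HEAD: "head", NECK: "neck", DENDRITE: "dendrite",
              DENDRITE_FAR: "dendrite_far", 0: "er"}

# canonical faces of a tet (opposite each vertex), oriented outward for a
# positively oriented tet (v1-v0, v2-v0, v3-v0 right-handed)
_TET_FACES = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])


def tet_signed_volumes(vertices: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of tets, positive for right-handed vertex order."""
    a = vertices[tets[:, 1]] - vertices[tets[:, 0]]
    b = vertices[tets[:, 2]] - vertices[tets[:, 0]]
    c = vertices[tets[:, 3]] - vertices[tets[:, 0]]
    return np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0


def triangle_areas(vertices: np.ndarray, tris: np.ndarray) -> np.ndarray:
    a = vertices[tris[:, 1]] - vertices[tris[:, 0]]
    b = vertices[tris[:, 2]] - vertices[tris[:, 0]]
    return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)


def _face_key(faces: np.ndarray) -> np.ndarray:
    """Sorted-vertex view usable as a dictionary key / unique row."""
    return np.sort(faces, axis=1)


def boundary_faces_of(tets: np.ndarray) -> np.ndarray:
    """Faces belonging to exactly one tet of ``tets`` (outward-oriented)."""
    if len(tets) == 0:
        return np.empty((0, 3), dtype=int)
    faces = tets[:, _TET_FACES].reshape(-1, 3)
    key = _face_key(faces)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return faces[counts[inv] == 1]


def min_dihedral_angle(vertices: np.ndarray, tets: np.ndarray) -> float:
    """Smallest dihedral angle (degrees) over all tets."""
    if len(tets) == 0:
        return float("nan")
    # face normals per tet (4 faces)
    p = vertices[tets]  # (m,4,3)
    normals = np.empty((len(tets), 4, 3))
    for f in range(4):
        tri = p[:, _TET_FACES[f], :]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        normals[:, f, :] = n / (np.linalg.norm(n, axis=1, keepdims=True) + 1e-300)
    best = np.pi
    for i in range(4):
        for j in range(i + 1, 4):
            cosang = np.einsum("ij,ij->i", normals[:, i], normals[:, j])
            ang = np.pi - np.arccos(np.clip(cosang, -1.0, 1.0))  # interior dihedral
            best = min(best, float(ang.min()))
    return np.degrees(best)


@dataclass
class QualityReport:
    """Mesh sanity report; the solver requires watertight, hole-free input."""

    min_dihedral_angle: float
    n_holes: int
    n_duplicate_vertices: int
    n_nonmanifold_edges: int
    watertight: Dict[str, bool]
    n_inverted_tets: int = 0

    @property
    def ok(self) -> bool:
        return (
            self.n_holes == 0
            and self.n_nonmanifold_edges == 0
            and self.n_inverted_tets == 0
            and all(self.watertight.values())
        )


@dataclass
class MorphologyMetrics:
    """Morphometric summary of a labeled spine mesh (µm, µm², µm³)."""

    spine_volume: float
    head_volume: float
    sa_volume: float
    sa_surface_area: float
    er_surface_area: float
    psd_area: float
    neck_cross_section: float
    sa_neck_cross_section: float
    cross_section_ratio: float      # % of the neck section occupied by SA
    psd_to_dendrite_distance: float
    neck_diameter: float            # mean of three measurements along the neck

    def to_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class TetMesh:
    """Labeled tetrahedral mesh of a spine + dendrite (+ SA/ER) domain."""

    vertices: np.ndarray                 # (n, 3) µm
    tets: np.ndarray                     # (m, 4) int
    volume_subset: np.ndarray            # (m,) in {CYTOSOL, ER_LUMEN}
    zone: np.ndarray                     # (m,) zone code, 0 for ER tets
    meta: dict = field(default_factory=dict)

    # derived, filled by label_surfaces()
    boundary_tris: np.ndarray = None     # (k, 3) int, outward of cytosol/ER
    surface_subset: np.ndarray = None    # (k,) surface code
    boundary_owner: np.ndarray = None    # (k,) CYTOSOL or ER_LUMEN

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.tets = np.asarray(self.tets, dtype=np.int64)
        self.volume_subset = np.asarray(self.volume_subset, dtype=np.int8)
        self.zone = np.asarray(self.zone, dtype=np.int8)

    # ------------------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def tets_of(self, subset: int) -> np.ndarray:
        return self.tets[self.volume_subset == subset]

    def tet_volumes(self) -> np.ndarray:
        return tet_signed_volumes(self.vertices, self.tets)

    def subdomain_volume(self, subset: int) -> float:
        v = tet_signed_volumes(self.vertices, self.tets_of(subset))
        return float(v.sum())

    @property
    def has_er(self) -> bool:
        return bool(np.any(self.volume_subset == ER_LUMEN))

    # ------------------------------------------------------------------
    def label_surfaces(self) -> None:
        """Extract boundary/interface triangles and classify them.

        Labels: faces shared by the cytosol and ER subdomains -> ``erm``;
        outer faces on the dendrite end planes -> ``closed_end``; outer
        faces inside the PSD cap -> ``psd``; everything else -> ``pm``.
        ER outer faces (tubule ends) are ``closed_end``.
        """
        cyt = self.tets_of(CYTOSOL)
        er = self.tets_of(ER_LUMEN)
        cyt_bnd = boundary_faces_of(cyt)
        er_bnd = boundary_faces_of(er)

        er_keys = {tuple(f) for f in _face_key(er_bnd)} if len(er_bnd) else set()

        tris, labels, owner = [], [], []
        meta = self.meta
        x_ends = meta.get("x_ends")          # (xmin, xmax) of the dendrite
        psd_zmin = meta.get("psd_zmin")      # faces above this z are PSD
        tol = meta.get("end_tol", 1e-6)

        def classify_outer(face, centroid):
            if x_ends is not None and (
                abs(centroid[0] - x_ends[0]) < tol or abs(centroid[0] - x_ends[1]) < tol
            ):
                return CLOSED_END
            if psd_zmin is not None and centroid[2] >= psd_zmin:
                return PSD
            return PM

        cyt_keys = {tuple(f) for f in _face_key(cyt_bnd)} if len(cyt_bnd) else set()
        for f in cyt_bnd:
            k = tuple(np.sort(f))
            c = self.vertices[f].mean(axis=0)
            if k in er_keys:
                tris.append(f); labels.append(ERM); owner.append(CYTOSOL)
            else:
                tris.append(f); labels.append(classify_outer(f, c)); owner.append(CYTOSOL)
        for f in er_bnd:
            k = tuple(np.sort(f))
            if k in cyt_keys:
                continue  # ERM already recorded from the cytosol side
            tris.append(f); labels.append(CLOSED_END); owner.append(ER_LUMEN)

        self.boundary_tris = np.array(tris, dtype=np.int64).reshape(-1, 3)
        self.surface_subset = np.array(labels, dtype=np.int8)
        self.boundary_owner = np.array(owner, dtype=np.int8)

    def surface_tris(self, label: int, owner: Optional[int] = None) -> np.ndarray:
        if self.boundary_tris is None:
            self.label_surfaces()
        mask = self.surface_subset == label
        if owner is not None:
            mask &= self.boundary_owner == owner
        return self.boundary_tris[mask]

    def surface_area(self, label: int) -> float:
        tris = self.surface_tris(label)
        if len(tris) == 0:
            return 0.0
        return float(triangle_areas(self.vertices, tris).sum())

    # ------------------------------------------------------------------
    def validate(self) -> QualityReport:
        """Quality report: watertightness per subdomain, holes, duplicates."""
        vols = self.tet_volumes()
        n_inverted = int(np.sum(vols <= 0))

        # duplicate vertices (exact coincidence)
        _, counts = np.unique(
            np.round(self.vertices, 12), axis=0, return_counts=True
        )
        n_dup = int(np.sum(counts > 1))

        watertight = {}
        n_holes = 0
        n_nonmanifold = 0
        for code, name in VOLUME_NAMES.items():
            tets = self.tets_of(code)
            if len(tets) == 0:
                continue
            bnd = boundary_faces_of(tets)
            edges = np.sort(
                bnd[:, [[0, 1], [1, 2], [2, 0]]].reshape(-1, 2), axis=1
            )
            _, inv, counts = np.unique(edges, axis=0, return_inverse=True,
                                       return_counts=True)
            open_edges = int(np.sum(counts == 1))
            nm_edges = int(np.sum(counts > 2))
            n_nonmanifold += nm_edges
            # each hole contributes a closed loop of >= 3 open edges
            n_holes += open_edges // 3 if open_edges else 0
            watertight[name] = open_edges == 0
        return QualityReport(
            min_dihedral_angle=min_dihedral_angle(self.vertices, self.tets),
            n_holes=n_holes,
            n_duplicate_vertices=n_dup,
            n_nonmanifold_edges=n_nonmanifold,
            watertight=watertight,
            n_inverted_tets=n_inverted,
        )

    # ------------------------------------------------------------------
    def cross_section_area(self, z0: float, subset: int,
                           radius_max: Optional[float] = None) -> float:
        """Area of the plane z = z0 intersected with a volume subset.

        ``radius_max`` restricts to tets whose centroid lies within that
        cylindrical radius of the spine axis (used to isolate the neck).
        """
        tets = self.tets_of(subset)
        if len(tets) == 0:
            return 0.0
        p = self.vertices[tets]
        zs = p[..., 2]
        crossing = (zs.min(axis=1) < z0) & (zs.max(axis=1) > z0)
        if radius_max is not None:
            cent = p.mean(axis=1)
            crossing &= np.hypot(cent[:, 0], cent[:, 1]) <= radius_max
        area = 0.0
        for tet_pts in p[crossing]:
            area += _tet_plane_section_area(tet_pts, z0)
        return float(area)


def _tet_plane_section_area(pts: np.ndarray, z0: float) -> float:
    """Area of the polygon where plane z=z0 cuts a single tet."""
    d = pts[:, 2] - z0
    below = d < 0
    pts_poly = []
    for i in range(4):
        for j in range(i + 1, 4):
            if below[i] != below[j]:
                t = d[i] / (d[i] - d[j])
                pts_poly.append(pts[i] + t * (pts[j] - pts[i]))
    if len(pts_poly) < 3:
        return 0.0
    poly = np.array(pts_poly)[:, :2]  # planar polygon in (x, y)
    centroid = poly.mean(axis=0)
    v = poly - centroid
    ang = np.arctan2(v[:, 1], v[:, 0])
    order = np.argsort(ang)
    poly = poly[order]
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
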