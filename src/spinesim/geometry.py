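"""Synthetic spine geometries, morphometrics, and surface I/O.

The generator emits an idealized SA-containing spine: a spherical head on
a cylindrical neck inserted into a cylindrical dendrite (axis x), with
the spine apparatus modeled as a capped tube running from a standardized
dendritic ER tubule through the neck into the lower head, where it may
end in a small bulge.  The PSD is a spherical-cap patch at the head apex.
Coordinates are µm; the spine axis is z and the spine base (neck
insertion) is at the origin, so the dendritic surface is tangent to the
plane z = 0.

Parameter ranges are chosen to bracket measured human SA-containing
spines: neck cross-sections of order 0.01-0.3 µm², SA occupying 3-49% of
the neck cross-section, spine volumes of order 0.1-1 µm³, and a dendrite
of about 1 µm width.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
import trimesh
from scipy import stats

from . import meshing
from .mesh import (
    CYTOSOL, DENDRITE, DENDRITE_FAR, ER_LUMEN, HEAD, NECK,
    MorphologyMetrics, QualityReport, TetMesh, boundary_faces_of,
    tet_signed_volumes, triangle_areas,
)


class GeometryError(ValueError):
    """Raised for geometrically infeasible spine parameters."""


@dataclass
class SpineParams:
    """Parametric description of a synthetic spine + SA geometry (µm)."""

    head_radius: float = 0.25
    neck_length: float = 0.45
    neck_radius: float = 0.15
    dendrite_radius: float = 0.5
    dendrite_length: float = 2.0
    sa_neck_radius: float = 0.07
    sa_head_radius: float = 0.08
    er_tubule_radius: float = 0.08
    psd_area: float = 0.09           # µm²
    target_edge_length_dendrite: float = 0.05
    target_edge_length_spine: float = 0.05
    include_sa: bool = True

    def __post_init__(self):
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "include_sa":
                continue
            if v <= 0:
                raise GeometryError(f"{f.name} must be > 0, got {v}")
        if self.include_sa and self.sa_neck_radius >= self.neck_radius:
            raise GeometryError(
                "sa_neck_radius must be < neck_radius (SA needs a cytosolic annulus)"
            )
        if self.er_tubule_radius >= self.dendrite_radius:
            raise GeometryError("er_tubule_radius must be < dendrite_radius")
        if self.neck_radius >= self.head_radius:
            raise GeometryError("neck_radius must be < head_radius")
        head_area = 4 * np.pi * self.head_radius**2
        if self.psd_area >= head_area:
            raise GeometryError("psd_area must be smaller than the head surface")
        if self.include_sa:
            # the SA bulge must sit strictly inside the outer surface:
            # sample its sphere and test against the outer SDF
            zb = self.sa_bulge_center_z
            th = np.linspace(0, np.pi, 24)
            ph = np.linspace(0, 2 * np.pi, 24, endpoint=False)
            T, P = np.meshgrid(th, ph)
            r = self.sa_head_radius
            pts = np.column_stack([
                (r * np.sin(T) * np.cos(P)).ravel(),
                (r * np.sin(T) * np.sin(P)).ravel(),
                zb + (r * np.cos(T)).ravel(),
            ])
            if np.any(self.phi_outer(pts) >= 0):
                raise GeometryError(
                    "SA head bulge does not fit inside the spine; "
                    "reduce sa_head_radius"
                )

    # derived geometry ------------------------------------------------
    @property
    def head_center_z(self) -> float:
        """Sphere center: the neck cylinder meets the head where the
        sphere's cross-section equals the neck radius."""
        return self.neck_length + np.sqrt(
            self.head_radius**2 - self.neck_radius**2
        )

    @property
    def sa_bulge_center_z(self) -> float:
        return self.neck_length + 0.5 * self.sa_head_radius

    @property
    def psd_cap_height(self) -> float:
        return self.psd_area / (2 * np.pi * self.head_radius)

    def replace(self, **kw) -> "SpineParams":
        return dataclasses.replace(self, **kw)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "SpineParams":
        return cls(**json.loads(s))

    # SDFs -------------------------------------------------------------
    def phi_outer(self, p: np.ndarray) -> np.ndarray:
        zd = -self.dendrite_radius
        dend = meshing.sdf_cylinder_x(p, 0.0, zd, self.dendrite_radius,
                                      self.dendrite_length / 2)
        neck = meshing.sdf_cylinder_z(p, 0.0, 0.0, self.neck_radius,
                                      zd, self.neck_length)
        head = meshing.sdf_sphere(p, (0.0, 0.0, self.head_center_z),
                                  self.head_radius)
        return meshing.sdf_union(dend, neck, head)

    def phi_er(self, p: np.ndarray) -> np.ndarray:
        zd = -self.dendrite_radius
        # tubule extended past the dendrite ends so its caps land exactly
        # on the (already clipped) closed end planes
        tub = meshing.sdf_cylinder_x(p, 0.0, zd, self.er_tubule_radius,
                                     self.dendrite_length / 2
                                     + 4 * self.target_edge_length_dendrite)
        if not self.include_sa:
            return tub
        stem = meshing.sdf_capsule_z(p, 0.0, 0.0, zd, self.sa_bulge_center_z,
                                     self.sa_neck_radius)
        bulge = meshing.sdf_sphere(p, (0.0, 0.0, self.sa_bulge_center_z),
                                   self.sa_head_radius)
        return meshing.sdf_union(tub, stem, bulge)


def widen_neck(params: SpineParams, pct: float) -> SpineParams:
    """Neck radius scaled by (1 + pct/100); SA and everything else fixed."""
    if pct < 0:
        raise ValueError("pct must be >= 0")
    return params.replace(neck_radius=params.neck_radius * (1 + pct / 100.0))


def build_synthetic_spine(params: SpineParams) -> TetMesh:
    """Generate the labeled tetrahedral mesh for ``params``.

    Zones are assigned by axial position of cytosolic tet centroids:
    z <= 0 dendrite (measuring zone within ±0.5 µm of the insertion,
    ``dendrite_far`` beyond), 0 < z <= neck_length neck, above that head.
    """
    h = params.target_edge_length_spine
    zd = -params.dendrite_radius
    margin = 2 * h
    bounds = np.array([
        [-params.dendrite_length / 2, -max(params.dendrite_radius,
                                           params.head_radius) - margin,
         zd - params.dendrite_radius - margin],
        [params.dendrite_length / 2, max(params.dendrite_radius,
                                         params.head_radius) + margin,
         params.head_center_z + params.head_radius + margin],
    ])
    verts, tets, phase = meshing.mesh_two_phase(
        bounds, h, params.phi_outer, params.phi_er
    )
    if len(tets) == 0:
        raise GeometryError(
            f"meshing produced no tetrahedra at edge length {h}; "
            "the spine is unresolvable at this resolution"
        )
    volume_subset = np.where(phase == 2, ER_LUMEN, CYTOSOL).astype(np.int8)
    if params.include_sa and not np.any(volume_subset == ER_LUMEN):
        raise GeometryError(
            f"the SA/ER (radius {params.sa_neck_radius} µm) was lost at edge "
            f"length {h}; refine target_edge_length_spine"
        )

    verts, tets, volume_subset = _prune_small_components(verts, tets,
                                                         volume_subset)

    cent = verts[tets].mean(axis=1)
    zone = np.zeros(len(tets), dtype=np.int8)
    cyt = volume_subset == CYTOSOL
    z = cent[:, 2]
    zone[cyt & (z > params.neck_length)] = HEAD
    zone[cyt & (z > 0) & (z <= params.neck_length)] = NECK
    zone[cyt & (z <= 0) & (np.abs(cent[:, 0]) <= 0.5)] = DENDRITE
    zone[cyt & (z <= 0) & (np.abs(cent[:, 0]) > 0.5)] = DENDRITE_FAR

    mesh = TetMesh(
        vertices=verts, tets=tets, volume_subset=volume_subset, zone=zone,
        meta={
            "params": dataclasses.asdict(params),
            "x_ends": (-params.dendrite_length / 2, params.dendrite_length / 2),
            "psd_zmin": params.head_center_z + params.head_radius
            - params.psd_cap_height,
            "end_tol": h / 2,
            "spine_base": (0.0, 0.0, 0.0),
            "neck_z_range": (0.0, params.neck_length),
            "neck_radius": params.neck_radius,
        },
    )
    mesh.label_surfaces()
    from .mesh import PSD
    if not np.any(mesh.surface_subset == PSD):
        raise GeometryError("PSD patch unresolved; enlarge psd_area or refine mesh")
    return mesh


def _prune_small_components(verts, tets, subset, min_frac: float = 0.01):
    """Drop face-connected components below ``min_frac`` of their phase."""
    keep = np.ones(len(tets), dtype=bool)
    vols = tet_signed_volumes(verts, tets)
    for code in (CYTOSOL, ER_LUMEN):
        idx = np.flatnonzero(subset == code)
        if len(idx) == 0:
            continue
        comp = _face_components(tets[idx])
        total = vols[idx].sum()
        for cid in np.unique(comp):
            sel = idx[comp == cid]
            if vols[sel].sum() < min_frac * total:
                keep[sel] = False
    tets, subset = tets[keep], subset[keep]
    used, inv = np.unique(tets, return_inverse=True)
    return verts[used], inv.reshape(tets.shape), subset


def _face_components(tets: np.ndarray) -> np.ndarray:
    """Connected components of tets linked through shared faces."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    faces = np.sort(tets[:, [[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]]]
                    .reshape(-1, 3), axis=1)
    owner = np.repeat(np.arange(len(tets)), 4)
    _, inv, counts = np.unique(faces, axis=0, return_inverse=True,
                               return_counts=True)
    order = np.argsort(inv, kind="stable")
    shared = counts == 2
    # pairs of owners for shared faces
    inv_sorted = inv[order]
    owner_sorted = owner[order]
    starts = np.searchsorted(inv_sorted, np.flatnonzero(shared))
    a = owner_sorted[starts]
    b = owner_sorted[starts + 1]
    n = len(tets)
    adj = coo_matrix((np.ones(len(a)), (a, b)), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    return labels


def reference_spine(desk_scale: bool = True) -> SpineParams:
    """The reference synthetic spine used in the sweep experiments.

    A long thin-necked SA-containing spine whose SA/neck cross-section
    ratio is ≈ 21% (the mid-range of measured human spines) and whose
    passive zone peaks (head ≈ 5 µM, dendrite ≈ 0.1 µM under the
    standard synaptic pulse) match the reconstructed-spine regime.  The
    desk-scale variant shortens the dendritic segment and coarsens the
    mesh so a full RyR-density sweep runs on one CPU in minutes; the
    full-scale variant keeps the ~1 µm dendrite at finer resolution.
    """
    if desk_scale:
        return SpineParams(
            head_radius=0.3, neck_length=1.1, neck_radius=0.12,
            dendrite_radius=0.42, dendrite_length=1.0,
            sa_neck_radius=0.055, sa_head_radius=0.065,
            er_tubule_radius=0.09, psd_area=0.09,
            target_edge_length_dendrite=0.095, target_edge_length_spine=0.095,
        )
    return SpineParams(
        head_radius=0.3, neck_length=1.1, neck_radius=0.12,
        dendrite_radius=0.5, dendrite_length=2.0,
        sa_neck_radius=0.055, sa_head_radius=0.065,
        er_tubule_radius=0.09, psd_area=0.09,
        target_edge_length_dendrite=0.05, target_edge_length_spine=0.05,
    )


# ----------------------------------------------------------------------
# morphometrics

def measure_morphology(mesh: TetMesh) -> MorphologyMetrics:
    """Morphometric quantities of a labeled spine mesh.

    Volumes sum signed tet volumes per subset; areas sum labeled boundary
    triangles; neck and SA cross-sections are measured on the plane
    through the neck axial midpoint (normal to the spine axis); the
    PSD-to-dendrite distance is the Euclidean distance from the PSD point
    nearest the spine base to the base.
    """
    from .mesh import ERM, PSD

    if mesh.boundary_tris is None:
        mesh.label_surfaces()
    missing = []
    if not np.any(mesh.volume_subset == CYTOSOL):
        missing.append("cytosol")
    if not np.any(mesh.zone == NECK):
        missing.append("neck zone")
    if not np.any(mesh.surface_subset == PSD):
        missing.append("psd")
    if missing:
        raise ValueError(f"mesh is missing subset labels: {', '.join(missing)}")

    vols = mesh.tet_volumes()
    cent = mesh.vertices[mesh.tets].mean(axis=1)
    cyt = mesh.volume_subset == CYTOSOL
    er = mesh.volume_subset == ER_LUMEN

    spine_cyt = cyt & np.isin(mesh.zone, (HEAD, NECK))
    head_cyt = cyt & (mesh.zone == HEAD)
    er_in_spine = er & (cent[:, 2] > 0)

    z_lo, z_hi = mesh.meta.get("neck_z_range", _infer_neck_range(mesh, cent))
    head_split = z_hi

    spine_volume = vols[spine_cyt].sum() + vols[er_in_spine].sum()
    head_volume = vols[head_cyt].sum() + vols[er & (cent[:, 2] > head_split)].sum()
    sa_volume = vols[er_in_spine].sum()

    erm_tris = mesh.surface_tris(ERM)
    erm_areas = triangle_areas(mesh.vertices, erm_tris) if len(erm_tris) else np.array([])
    er_surface = float(erm_areas.sum())
    if len(erm_tris):
        tri_cent = mesh.vertices[erm_tris].mean(axis=1)
        sa_surface = float(erm_areas[tri_cent[:, 2] > 0].sum())
    else:
        sa_surface = 0.0

    z_mid = 0.5 * (z_lo + z_hi)
    neck_cyt_area = mesh.cross_section_area(z_mid, CYTOSOL)
    sa_area = mesh.cross_section_area(z_mid, ER_LUMEN)
    neck_area = neck_cyt_area + sa_area

    diam = []
    for frac in (0.25, 0.5, 0.75):
        zq = z_lo + frac * (z_hi - z_lo)
        a = mesh.cross_section_area(zq, CYTOSOL) + mesh.cross_section_area(zq, ER_LUMEN)
        diam.append(2 * np.sqrt(a / np.pi))

    base = np.asarray(mesh.meta.get("spine_base", (0.0, 0.0, 0.0)))
    psd_verts = mesh.vertices[np.unique(mesh.surface_tris(PSD))]
    psd_dist = float(np.min(np.linalg.norm(psd_verts - base, axis=1)))

    return MorphologyMetrics(
        spine_volume=float(spine_volume),
        head_volume=float(head_volume),
        sa_volume=float(sa_volume),
        sa_surface_area=sa_surface,
        er_surface_area=er_surface,
        psd_area=mesh.surface_area(PSD),
        neck_cross_section=float(neck_area),
        sa_neck_cross_section=float(sa_area),
        cross_section_ratio=100.0 * sa_area / neck_area if neck_area else 0.0,
        psd_to_dendrite_distance=psd_dist,
        neck_diameter=float(np.mean(diam)),
    )


def _infer_neck_range(mesh: TetMesh, cent: np.ndarray) -> Tuple[float, float]:
    zn = cent[mesh.zone == NECK][:, 2]
    return float(zn.min()), float(zn.max())


def cross_section_ratio(sa_neck_area: float, neck_area: float) -> float:
    """Percentage of the neck cross-section occupied by the SA."""
    if neck_area <= 0:
        raise ValueError("neck area must be positive")
    return 100.0 * sa_neck_area / neck_area


# ----------------------------------------------------------------------
# validation & I/O

def validate_mesh(mesh) -> QualityReport:
    """Quality report for a TetMesh or a triangular surface mesh."""
    if isinstance(mesh, TetMesh):
        return mesh.validate()
    if isinstance(mesh, trimesh.Trimesh):
        verts, faces = np.asarray(mesh.vertices), np.asarray(mesh.faces)
    else:
        verts, faces = (np.asarray(x) for x in mesh)
    edges = np.sort(faces[:, [[0, 1], [1, 2], [2, 0]]].reshape(-1, 2), axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    open_edges = int(np.sum(counts == 1))
    nonmanifold = int(np.sum(counts > 2))
    _, vcounts = np.unique(np.round(verts, 12), axis=0, return_counts=True)
    return QualityReport(
        min_dihedral_angle=float("nan"),
        n_holes=open_edges // 3 if open_edges else 0,
        n_duplicate_vertices=int(np.sum(vcounts > 1)),
        n_nonmanifold_edges=nonmanifold,
        watertight={"surface": open_edges == 0},
    )


def load_surface_mesh(path) -> Dict[str, trimesh.Trimesh]:
    """Load a grouped OBJ surface as {group name: triangle mesh}.

    Faces must be triangles (an error names the first offending face);
    geometry outside any named group is returned under ``unassigned``.
    Groups are read from ``o``/``g`` records; the surfaces are meant as
    input to an external tetrahedralizer -- no remeshing or repair is
    performed here.
    """
    import warnings

    groups: Dict[str, List[List[int]]] = {}
    verts: List[List[float]] = []
    current = "unassigned"
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "v":
                verts.append([float(x) for x in parts[1:4]])
            elif parts[0] in ("o", "g"):
                current = parts[1] if len(parts) > 1 else "unassigned"
            elif parts[0] == "f":
                refs = parts[1:]
                if len(refs) != 3:
                    raise ValueError(
                        f"non-triangular face at line {ln} of {path} "
                        f"({len(refs)} vertices)"
                    )
                idx = [int(r.split("/")[0]) - 1 for r in refs]
                groups.setdefault(current, []).append(idx)
    if not verts:
        raise ValueError(f"{path} contains no vertices")
    varr = np.asarray(verts, float)
    out = {}
    for name, faces in groups.items():
        if name == "unassigned" and len(groups) > 1:
            warnings.warn(f"{path}: faces outside any named group "
                          "labeled 'unassigned'")
        out[name] = trimesh.Trimesh(vertices=varr, faces=np.asarray(faces),
                                    process=False)
    return out


def save_surface_mesh(path, mesh: TetMesh) -> None:
    """Export the labeled boundary of a TetMesh as a grouped OBJ file."""
    from .mesh import SURFACE_NAMES

    if mesh.boundary_tris is None:
        mesh.label_surfaces()
    with open(path, "w") as fh:
        fh.write("# spinesim labeled surface\n")
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for code, name in SURFACE_NAMES.items():
            tris = mesh.surface_tris(code)
            if len(tris) == 0:
                continue
            fh.write(f"o {name}\n")
            for t in tris:
                fh.write(f"f {t[0] + 1} {t[1] + 1} {t[2] + 1}\n")


# ----------------------------------------------------------------------
# regressions over spine cohorts

def morphometric_regressions(
    metrics: Sequence[MorphologyMetrics],
    pairs: Iterable[Tuple[str, str]],
) -> pd.DataFrame:
    """Ordinary least-squares fits between morphometric fields.

    One row per (x, y) pair: slope, intercept, Pearson correlation, and
    the t statistic for slope-different-from-zero.
    """
    if len(metrics) < 3:
        raise ValueError("need at least 3 spine records for a regression")
    table = pd.DataFrame([m.to_dict() for m in metrics])
    rows = []
    for x, y in pairs:
        xv, yv = table[x].to_numpy(), table[y].to_numpy()
        if np.ptp(xv) == 0:
            raise ValueError(f"degenerate regression: predictor {x!r} is constant")
        fit = stats.linregress(xv, yv)
        t_stat = fit.slope / fit.stderr if fit.stderr > 0 else np.inf
        rows.append({
            "x": x, "y": y, "slope": fit.slope, "intercept": fit.intercept,
            "correlation": fit.rvalue, "t_slope": t_stat, "p_value": fit.pvalue,
            "n": len(xv),
        })
    return pd.DataFrame(rows)
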