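"""Export of meshes, fields and traces: VTU, Gmsh MSH, OBJ, CSV, JSON.

The VTU and MSH writers emit the plain ASCII flavours of those formats;
both are simple enough to write directly and keep the artifact free of
binary output.  Surfaces go through the grouped-OBJ writer in
:mod:`spinesim.geometry`.
"""

from __future__ import annotations

import json
from typing import Dict, Optional

import numpy as np

from .mesh import SURFACE_NAMES, TetMesh, VOLUME_NAMES, ZONE_NAMES


def write_vtu(path, mesh: TetMesh,
              point_data: Optional[Dict[str, np.ndarray]] = None,
              cell_data: Optional[Dict[str, np.ndarray]] = None) -> None:
    """Write the tet mesh (and optional nodal/cell fields) as ASCII VTU."""
    verts, tets = mesh.vertices, mesh.tets
    n_pts, n_cells = len(verts), len(tets)
    cell_data = dict(cell_data or {})
    cell_data.setdefault("volume_subset", mesh.volume_subset)
    cell_data.setdefault("zone", mesh.zone)

    def arr_to_text(a, fmt="{:.9g}"):
        a = np.asarray(a)
        flat = a.ravel()
        return " ".join(fmt.format(x) for x in flat)

    with open(path, "w") as fh:
        fh.write('<?xml version="1.0"?>\n')
        fh.write('<VTKFile type="UnstructuredGrid" version="0.1" '
                 'byte_order="LittleEndian">\n')
        fh.write('  <UnstructuredGrid>\n')
        fh.write(f'    <Piece NumberOfPoints="{n_pts}" '
                 f'NumberOfCells="{n_cells}">\n')
        fh.write('      <Points>\n')
        fh.write('        <DataArray type="Float64" NumberOfComponents="3" '
                 'format="ascii">\n')
        fh.write(arr_to_text(verts) + "\n")
        fh.write('        </DataArray>\n      </Points>\n')
        fh.write('      <Cells>\n')
        fh.write('        <DataArray type="Int64" Name="connectivity" '
                 'format="ascii">\n')
        fh.write(arr_to_text(tets, "{:d}") + "\n")
        fh.write('        </DataArray>\n')
        fh.write('        <DataArray type="Int64" Name="offsets" '
                 'format="ascii">\n')
        fh.write(arr_to_text(4 * np.arange(1, n_cells + 1), "{:d}") + "\n")
        fh.write('        </DataArray>\n')
        fh.write('        <DataArray type="UInt8" Name="types" '
                 'format="ascii">\n')
        fh.write(" ".join(["10"] * n_cells) + "\n")  # VTK_TETRA
        fh.write('        </DataArray>\n      </Cells>\n')
        if point_data:
            fh.write('      <PointData>\n')
            for name, vals in point_data.items():
                fh.write(f'        <DataArray type="Float64" Name="{name}" '
                         'format="ascii">\n')
                fh.write(arr_to_text(vals) + "\n")
                fh.write('        </DataArray>\n')
            fh.write('      </PointData>\n')
        fh.write('      <CellData>\n')
        for name, vals in cell_data.items():
            fh.write(f'        <DataArray type="Int32" Name="{name}" '
                     'format="ascii">\n')
            fh.write(arr_to_text(vals.astype(int), "{:d}") + "\n")
            fh.write('        </DataArray>\n')
        fh.write('      </CellData>\n')
        fh.write('    </Piece>\n  </UnstructuredGrid>\n</VTKFile>\n')


def write_field_snapshots(prefix, mesh: TetMesh, dual, snapshots) -> list:
    """Write VTU time series of (t, FieldState) snapshots.

    Point data: cytosolic calcium, buffer, ER calcium and RyR open
    probability, padded with NaN on vertices outside the owning
    subdomain.  Returns the list of files written.
    """
    files = []
    for i, (t, state) in enumerate(snapshots):
        nv = mesh.n_vertices
        cc = np.full(nv, np.nan)
        b = np.full(nv, np.nan)
        ce = np.full(nv, np.nan)
        po = np.full(nv, np.nan)
        cc[dual.cyt_verts] = state.c_c
        b[dual.cyt_verts] = state.b
        if dual.n_e:
            ce[dual.er_verts] = state.c_e
            po[dual.cyt_verts[dual.erm_c]] = state.gating.open_probability
        path = f"{prefix}_{i:04d}.vtu"
        write_vtu(path, mesh, point_data={"c_c_uM": cc, "b_uM": b,
                                          "c_e_uM": ce, "ryr_open_prob": po})
        files.append(path)
    return files


def write_msh(path, mesh: TetMesh) -> None:
    """Write the labeled tet mesh in Gmsh 2.2 ASCII format.

    Volume subsets become physical tags on the tets; labeled boundary
    triangles are appended with their surface-subset tags.
    """
    if mesh.boundary_tris is None:
        mesh.label_surfaces()
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        names = [(1, code + 10, name) for code, name in SURFACE_NAMES.items()]
        names += [(3, code, name) for code, name in VOLUME_NAMES.items()]
        fh.write(f"$PhysicalNames\n{len(names)}\n")
        for dim, tag, name in names:
            fh.write(f'{dim} {tag} "{name}"\n')
        fh.write("$EndPhysicalNames\n")
        fh.write(f"$Nodes\n{mesh.n_vertices}\n")
        for i, v in enumerate(mesh.vertices, start=1):
            fh.write(f"{i} {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        fh.write("$EndNodes\n")
        n_elem = mesh.n_tets + len(mesh.boundary_tris)
        fh.write(f"$Elements\n{n_elem}\n")
        eid = 1
        for tri, lab in zip(mesh.boundary_tris, mesh.surface_subset):
            tag = int(lab) + 10
            fh.write(f"{eid} 2 2 {tag} {tag} "
                     f"{tri[0] + 1} {tri[1] + 1} {tri[2] + 1}\n")
            eid += 1
        for tet, lab in zip(mesh.tets, mesh.volume_subset):
            fh.write(f"{eid} 4 2 {int(lab)} {int(lab)} "
                     f"{tet[0] + 1} {tet[1] + 1} {tet[2] + 1} {tet[3] + 1}\n")
            eid += 1
        fh.write("$EndElements\n")


def write_run_metadata(path, config, params, extra: Optional[dict] = None) -> None:
    """JSON metadata: configuration, parameter set + hash, extras."""
    doc = {
        "config": config.to_dict(),
        "parameters": params.to_dict(),
        "parameter_hash": params.content_hash(),
    }
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True, default=str)
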