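"""File formats: NIfTI volumes, VTK/PLY meshes, CSV point tables, JSON/YAML.

Volumes are NIfTI-1 with the affine honored (axis-aligned affines only —
the voxel lattice container is axis-aligned by design).  Meshes go out as
legacy-ASCII VTK polydata with per-vertex scalar arrays, or PLY via
trimesh.  Point tables are CSV with the documented schema
``x, y, z, time_ms, category, label``.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grid import Volume
from .registration import RigidTransform
from .surface import SurfaceMesh

POINT_COLUMNS = ("x", "y", "z", "time_ms", "category", "label")


def read_volume(path) -> Volume:
    """Read a NIfTI volume into the axis-aligned lattice container."""
    img = nib.load(str(path))
    affine = img.affine
    linear = affine[:3, :3]
    off_diag = linear - np.diag(np.diag(linear))
    if np.max(np.abs(off_diag)) > 1e-6:
        raise ValueError(
            "affine: only axis-aligned (diagonal) affines are supported; "
            f"off-diagonal terms up to {np.max(np.abs(off_diag)):.3g} found"
        )
    spacing = np.diag(linear)
    if np.any(spacing <= 0):
        raise ValueError(f"affine: non-positive voxel scales {tuple(spacing)}")
    data = np.asarray(img.dataobj)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.int16)
    return Volume(data, tuple(spacing), tuple(affine[:3, 3]))


def write_volume(vol: Volume, path) -> None:
    data = vol.data
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.int16)
    img = nib.Nifti1Image(data, vol.affine)
    nib.save(img, str(path))


def read_points(path) -> pd.DataFrame:
    """Read an electroanatomic point table, validating the schema."""
    df = pd.read_csv(path)
    for col in POINT_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"point table is missing required column {col!r}")
    df["label"] = df["label"].fillna("")
    return df


def write_points(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_mesh_vtk(mesh: SurfaceMesh, path) -> None:
    """Legacy-ASCII VTK polydata with per-vertex scalar arrays."""
    v = mesh.vertices
    f = mesh.faces
    lines = [
        "# vtk DataFile Version 3.0",
        "vtsubstrate surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(v)} float",
    ]
    lines += [" ".join(f"{c:.6f}" for c in row) for row in v]
    lines.append(f"POLYGONS {len(f)} {4 * len(f)}")
    lines += ["3 " + " ".join(str(i) for i in row) for row in f]
    if mesh.vertex_data:
        lines.append(f"POINT_DATA {len(v)}")
        for name, arr in mesh.vertex_data.items():
            arr = np.asarray(arr, dtype=float)
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{x:.6f}" for x in arr]
    Path(path).write_text("\n".join(lines) + "\n")


def write_mesh_ply(mesh: SurfaceMesh, path) -> None:
    mesh.trimesh.export(str(path), file_type="ply", encoding="ascii")


def write_transform(transform: RigidTransform, path) -> None:
    Path(path).write_text(json.dumps(transform.to_dict(), indent=2))


def read_transform(path) -> RigidTransform:
    return RigidTransform.from_dict(json.loads(Path(path).read_text()))
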