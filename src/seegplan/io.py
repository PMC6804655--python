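"""NIfTI volumes, STL/PLY meshes and JSON sidecars.

Volumes round-trip through NIfTI-1 with the grid encoded in the affine;
meshes through trimesh (STL or PLY), with per-vertex radii carried as a
JSON sidecar next to the mesh file (STL has no vertex attributes, and a
sidecar keeps the two formats interchangeable).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import trimesh as _trimesh

from .grids import Grid
from .mesh import SurfaceMesh


def write_volume(path, volume: np.ndarray, grid: Grid) -> None:
    volume = np.asarray(volume)
    if volume.dtype == bool:
        volume = volume.astype(np.uint8)
    img = nib.Nifti1Image(volume, grid.affine)
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))


def read_volume(path) -> tuple[np.ndarray, Grid]:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - delegated validation
        raise ValueError(f"cannot read NIfTI volume at {path}: {exc}") from exc
    data = np.asarray(img.dataobj)
    grid = Grid.from_affine(tuple(data.shape), img.affine)
    return data, grid


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".radii.json")


def write_mesh(path, mesh: SurfaceMesh) -> None:
    """STL or PLY plus a JSON radii sidecar.

    The sidecar stores vertex positions alongside the radii because some
    formats (STL in particular) deduplicate and reorder vertices on read;
    radii are re-attached by nearest-position matching.
    """
    path = Path(path)
    tm = _trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(str(path))
    if mesh.vertex_radius is not None:
        _sidecar(path).write_text(
            json.dumps(
                {
                    "vertices_mm": mesh.vertices.tolist(),
                    "vertex_radius_mm": mesh.vertex_radius.tolist(),
                }
            )
        )


def read_mesh(path) -> SurfaceMesh:
    path = Path(path)
    try:
        tm = _trimesh.load_mesh(str(path), process=False)
        verts = np.asarray(tm.vertices, dtype=float)
        faces = np.asarray(tm.faces, dtype=np.int64)
    except Exception as exc:
        raise ValueError(f"cannot read mesh at {path}: {exc}") from exc
    if verts.size == 0:
        raise ValueError(f"cannot read mesh at {path}: no geometry found")
    radius = None
    sc = _sidecar(path)
    if sc.exists():
        side = json.loads(sc.read_text())
        rad = np.asarray(side["vertex_radius_mm"], dtype=float)
        if len(rad) == len(verts):
            radius = rad
        else:
            from scipy.spatial import cKDTree

            tree = cKDTree(np.asarray(side["vertices_mm"], dtype=float))
            _, idx = tree.query(verts)
            radius = rad[idx]
    return SurfaceMesh(verts, faces, radius)


def write_tree_json(path, tree) -> None:
    Path(path).write_text(json.dumps(tree.to_dict()))


def read_tree_json(path):
    from .phantom import VascularTree

    return VascularTree.from_dict(json.loads(Path(path).read_text()))
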