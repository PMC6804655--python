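"""Critical-structure model generation from modality volumes.

The chain mirrors a clinical vascular-model workflow: vesselness filtering,
intracranial masking, isosurface extraction, removal of small disconnected
components, centreline-based radius attribution, and diameter pruning.
A sulcal surface model (deep gray matter after eroding the intracranial
mask) stands in for vessels hidden inside sulci.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure, morphology, filters

from .grids import Grid
from .mesh import SurfaceMesh, voxelize_closed_mesh
from .vesselness import VesselnessParams, sato_vesselness

__all__ = [
    "sato_vesselness",
    "VesselnessParams",
    "apply_intracranial_mask",
    "extract_vessel_surface",
    "remove_small_components",
    "extract_sulcal_model",
    "extract_centerline_radii",
    "prune_by_diameter",
    "segment_vessels",
]


def apply_intracranial_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero every voxel outside the binary mask (extracranial removal)."""
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError(
            f"grid mismatch: image {image.shape} vs mask {mask.shape}"
        )
    return np.where(mask, image, 0.0)


def extract_vessel_surface(
    vesselness: np.ndarray, grid: Grid, threshold: float
) -> SurfaceMesh:
    """Marching-cubes isosurface of the vesselness volume at ``threshold``.

    Vertex coordinates are in mm (grid origin and spacing applied).  The
    threshold must lie inside the volume's intensity range; an in-range
    threshold that produces no surface yields an empty mesh with a warning.
    """
    vol = np.asarray(vesselness, dtype=float)
    lo, hi = float(vol.min()), float(vol.max())
    if not (lo <= threshold <= hi):
        raise ValueError(
            f"threshold {threshold} outside intensity range [{lo}, {hi}]"
        )
    try:
        verts, faces, _, _ = measure.marching_cubes(vol, level=threshold)
    except (ValueError, RuntimeError):
        warnings.warn("empty isosurface at the requested threshold")
        return SurfaceMesh.empty()
    if len(faces) == 0:
        warnings.warn("empty isosurface at the requested threshold")
        return SurfaceMesh.empty()
    return SurfaceMesh(grid.voxel_to_world(verts), faces)


def remove_small_components(mesh: SurfaceMesh, min_vertices: int = 30) -> SurfaceMesh:
    """Delete connected components with fewer than ``min_vertices`` vertices."""
    if min_vertices < 0:
        raise ValueError("min_vertices must be >= 0")
    if min_vertices == 0 or mesh.n_vertices == 0:
        return mesh.copy()
    labels = mesh.vertex_components()
    counts = np.bincount(labels)
    keep = counts[labels] >= min_vertices
    return mesh.submesh(keep)


def extract_sulcal_model(
    gm_mask: np.ndarray,
    intracranial_mask: np.ndarray,
    grid: Grid,
    erosion_mm: float = 5.0,
) -> SurfaceMesh:
    """Surface of deep gray matter: GM intersected with the eroded ICV mask.

    Superficial cortex vanishes under the erosion; what survives are the
    sulcal infoldings deeper than ``erosion_mm`` — the proxy model for
    vessels running inside sulci.
    """
    gm = np.asarray(gm_mask, dtype=bool)
    icv = np.asarray(intracranial_mask, dtype=bool)
    if gm.shape != icv.shape:
        raise ValueError("gm and intracranial masks must share a grid")
    if erosion_mm < 0:
        raise ValueError("erosion_mm must be >= 0")
    if erosion_mm == 0:
        deep = gm
    else:
        rad_vox = erosion_mm / min(grid.spacing)
        selem = morphology.ball(int(round(rad_vox)))
        eroded = ndimage.binary_erosion(icv, structure=selem)
        deep = gm & eroded
    if not deep.any():
        warnings.warn("erosion removed all gray matter; sulcal model is empty")
        return SurfaceMesh.empty()
    verts, faces, _, _ = measure.marching_cubes(deep.astype(float), level=0.5)
    return SurfaceMesh(grid.voxel_to_world(verts), faces)


def extract_centerline_radii(mesh: SurfaceMesh, grid: Grid) -> SurfaceMesh:
    """Attach per-vertex radii = distance to the extracted centreline.

    The mesh interior is voxelised on ``grid`` and its medial curve taken
    as the ridge of the interior Euclidean distance transform (voxels
    within a quarter voxel of the local 3x3x3 depth maximum, on a 2x
    refined lattice so vessels one-two voxels across keep a distinct
    axis).  Discrete ridges carry shallow spurious points, so each vertex
    is matched to its medial ball — the ridge point p minimising the
    power distance ``|v - p| - depth(p)`` — and the radius is the
    distance to that point.  For a cylinder this recovers the tube
    radius; for a sphere the ridge collapses to the centre and radii
    approximate the sphere radius.
    """
    if mesh.is_empty:
        raise ValueError("cannot extract a centerline from an empty mesh")
    filled = voxelize_closed_mesh(mesh, grid)
    fine = np.repeat(np.repeat(np.repeat(filled, 2, 0), 2, 1), 2, 2)
    fine_spacing = grid.spacing_arr / 2.0
    edt = ndimage.distance_transform_edt(fine, sampling=fine_spacing)
    local_max = ndimage.maximum_filter(edt, size=3)
    ridge = fine & (edt >= local_max - 0.25 * float(fine_spacing.min()))
    if not ridge.any():
        ridge = np.zeros_like(fine)
        ridge[np.unravel_index(np.argmax(edt), edt.shape)] = True
    idx = np.array(np.nonzero(ridge)).T
    pts = grid.origin_arr + (idx + 0.5) * fine_spacing
    depth = edt[ridge]

    tree = cKDTree(pts)
    k = min(64, len(pts))
    _, knn = tree.query(mesh.vertices, k=k)
    knn = knn.reshape(len(mesh.vertices), k)
    # the deepest ridge points are candidate medial balls for everyone
    # (a sphere's centre is far from every surface vertex)
    deep = np.argsort(depth)[-min(64, len(pts)):]
    cand = np.concatenate([knn, np.broadcast_to(deep, (len(knn), len(deep)))], axis=1)
    d = np.linalg.norm(
        mesh.vertices[:, None, :] - pts[cand], axis=2
    )
    power = d - depth[cand]
    best = np.argmin(power, axis=1)
    radii = d[np.arange(len(d)), best]
    out = mesh.copy()
    out.vertex_radius = np.asarray(radii, dtype=float)
    return out


def prune_by_diameter(mesh: SurfaceMesh, threshold_mm: float) -> SurfaceMesh:
    """Remove vertices whose local diameter is strictly below the threshold.

    Faces touching a removed vertex are dropped.  The boundary is strict:
    a vertex at exactly the threshold diameter survives.  Threshold 0 is
    the identity.
    """
    if mesh.vertex_radius is None:
        raise ValueError("prune_by_diameter requires vertex_radius")
    if threshold_mm <= 0:
        return mesh.copy()
    keep = 2.0 * mesh.vertex_radius >= threshold_mm
    return mesh.submesh(keep)


def auto_threshold(vesselness: np.ndarray) -> float:
    """Otsu threshold over the strictly positive vesselness responses."""
    v = np.asarray(vesselness, dtype=float)
    pos = v[v > 0]
    if pos.size < 2:
        return float(v.max())
    return float(filters.threshold_otsu(pos))


def segment_vessels(
    image: np.ndarray,
    grid: Grid,
    intracranial_mask: np.ndarray,
    params: VesselnessParams | None = None,
    threshold: float | None = None,
    min_component_vertices: int = 30,
    compute_radii: bool = True,
) -> SurfaceMesh:
    """Full vessel-model chain from one modality volume to a cleaned mesh.

    vesselness -> intracranial masking -> isosurface at ``threshold`` (Otsu
    over positive responses when not given) -> small-component removal ->
    optional centreline radius attribution.
    """
    params = params or VesselnessParams()
    v = sato_vesselness(image, grid, params)
    v = apply_intracranial_mask(v, intracranial_mask)
    if threshold is None:
        threshold = auto_threshold(v)
    mesh = extract_vessel_surface(v, grid, threshold)
    mesh = remove_small_components(mesh, min_component_vertices)
    if compute_radii and not mesh.is_empty:
        mesh = extract_centerline_radii(mesh, grid)
    return mesh
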