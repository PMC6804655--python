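"""Triangle-mesh container and the geometry kernels the planner relies on.

:class:`SurfaceMesh` is a minimal vertices/faces container with an optional
per-vertex radius attribute (distance from the vessel surface to its
centreline, used for diameter pruning).  The heavy queries — exact
point-to-surface distance, segment/triangle intersection, voxelisation of a
closed surface — live here so that model generation, planning and evaluation
all share one implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .grids import Grid


@dataclass
class SurfaceMesh:
    """Triangle mesh in millimetre coordinates.

    Attributes
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array of vertex indices
    vertex_radius : optional (n,) float array
        Local tube radius at each vertex (mm); populated by centreline
        extraction and consumed by diameter pruning.
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_radius: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and self.faces.max(initial=-1) >= len(self.vertices):
            raise ValueError("face index out of range")
        if self.vertex_radius is not None:
            self.vertex_radius = np.asarray(self.vertex_radius, dtype=float).ravel()
            if len(self.vertex_radius) != len(self.vertices):
                raise ValueError("vertex_radius must have one value per vertex")

    # -- basic properties ----------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def is_empty(self) -> bool:
        return self.n_faces == 0

    def triangles(self) -> np.ndarray:
        """Face corner coordinates, shape (m, 3, 3)."""
        return self.vertices[self.faces]

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.vertex_radius is None else self.vertex_radius.copy(),
        )

    @classmethod
    def empty(cls) -> "SurfaceMesh":
        return cls(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64))

    def area(self) -> float:
        if self.is_empty:
            return 0.0
        tri = self.triangles()
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return float(0.5 * np.linalg.norm(cross, axis=1).sum())

    def remove_unreferenced_vertices(self) -> "SurfaceMesh":
        """Drop vertices not used by any face, remapping indices."""
        if self.n_faces == 0:
            rad = None if self.vertex_radius is None else np.zeros(0)
            return SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64), rad)
        used = np.unique(self.faces)
        remap = -np.ones(self.n_vertices, dtype=np.int64)
        remap[used] = np.arange(len(used))
        rad = None if self.vertex_radius is None else self.vertex_radius[used]
        return SurfaceMesh(self.vertices[used], remap[self.faces], rad)

    def vertex_components(self) -> np.ndarray:
        """Connected-component label per vertex (edge connectivity)."""
        n = self.n_vertices
        parent = np.arange(n)

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for f in self.faces:
            ra, rb, rc = find(f[0]), find(f[1]), find(f[2])
            parent[rb] = ra
            parent[find(rc)] = ra
        roots = np.array([find(i) for i in range(n)])
        _, labels = np.unique(roots, return_inverse=True)
        return labels

    def submesh(self, vertex_mask: np.ndarray) -> "SurfaceMesh":
        """Keep flagged vertices and the faces entirely inside the flag set."""
        vertex_mask = np.asarray(vertex_mask, dtype=bool)
        keep_faces = vertex_mask[self.faces].all(axis=1) if self.n_faces else np.zeros(0, bool)
        out = SurfaceMesh(self.vertices, self.faces[keep_faces], self.vertex_radius)
        return out.remove_unreferenced_vertices()


def concatenate_meshes(meshes: list[SurfaceMesh]) -> SurfaceMesh:
    meshes = [m for m in meshes if m.n_vertices]
    if not meshes:
        return SurfaceMesh.empty()
    verts = np.vstack([m.vertices for m in meshes])
    offs = np.cumsum([0] + [m.n_vertices for m in meshes[:-1]])
    faces = np.vstack([m.faces + o for m, o in zip(meshes, offs)])
    if all(m.vertex_radius is not None for m in meshes):
        rad = np.concatenate([m.vertex_radius for m in meshes])
    else:
        rad = None
    return SurfaceMesh(verts, faces, rad)


# ---------------------------------------------------------------------------
# Point -> surface distance
# ---------------------------------------------------------------------------

def _closest_point_on_triangles(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact squared distance from each point to its paired triangle.

    points: (k, 3); tri: (k, 3, 3).  Vectorised Ericson-style closest point
    on triangle; returns squared distances (k,).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = points - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = points - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = points - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    closest = np.empty_like(points)
    done = np.zeros(len(points), dtype=bool)

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    closest[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    closest[m] = b[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    closest[m] = c[m]
    done |= m

    # edge AB
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    denom = d1[m] - d3[m]
    t = np.where(denom > 0, d1[m] / np.where(denom > 0, denom, 1.0), 0.0)
    closest[m] = a[m] + t[:, None] * ab[m]
    done |= m

    # edge AC
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    denom = d2[m] - d6[m]
    t = np.where(denom > 0, d2[m] / np.where(denom > 0, denom, 1.0), 0.0)
    closest[m] = a[m] + t[:, None] * ac[m]
    done |= m

    # edge BC
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    denom = (d4[m] - d3[m]) + (d5[m] - d6[m])
    t = np.where(denom > 0, (d4[m] - d3[m]) / np.where(denom > 0, denom, 1.0), 0.0)
    closest[m] = b[m] + t[:, None] * (c[m] - b[m])
    done |= m

    # interior
    m = ~done
    denom = va[m] + vb[m] + vc[m]
    denom = np.where(np.abs(denom) > 1e-300, denom, 1.0)
    v = vb[m] / denom
    w = vc[m] / denom
    closest[m] = a[m] + v[:, None] * ab[m] + w[:, None] * ac[m]

    diff = points - closest
    return np.einsum("ij,ij->i", diff, diff)


def brute_force_surface_distance(points: np.ndarray, mesh: SurfaceMesh) -> np.ndarray:
    """Reference O(points x faces) distance; used as the oracle in tests."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if mesh.is_empty:
        return np.full(len(points), np.inf)
    tri = mesh.triangles()
    out = np.empty(len(points))
    chunk = max(1, int(2_000_000 // max(len(tri), 1)))
    for s in range(0, len(points), chunk):
        pts = points[s:s + chunk]
        m = len(pts)
        flat_pts = np.repeat(pts, len(tri), axis=0)
        flat_tri = np.tile(tri, (m, 1, 1))
        d2 = _closest_point_on_triangles(flat_pts, flat_tri).reshape(m, len(tri))
        out[s:s + chunk] = np.sqrt(d2.min(axis=1))
    return out


class MeshDistanceQuery:
    """Exact point-to-surface distances accelerated by KD-trees.

    The nearest mesh *vertex* gives a tight upper bound on the surface
    distance (vertices lie on the surface); every triangle whose centroid
    ball could undercut that bound is then evaluated exactly, so results
    match the brute-force oracle.
    """

    def __init__(self, mesh: SurfaceMesh):
        self.mesh = mesh
        if mesh.is_empty:
            self._tri = None
            return
        self._tri = mesh.triangles()
        self._centroids = self._tri.mean(axis=1)
        self._rmax = float(
            np.linalg.norm(self._tri - self._centroids[:, None, :], axis=2).max()
        )
        self._ctree = cKDTree(self._centroids)
        self._vtree = cKDTree(mesh.vertices[np.unique(mesh.faces)])

    def distances(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if self._tri is None:
            return np.full(len(points), np.inf)
        ub, _ = self._vtree.query(points)
        lists = self._ctree.query_ball_point(points, ub + self._rmax + 1e-9)
        counts = np.array([len(l) for l in lists])
        out = ub.copy()
        if counts.sum() == 0:
            return out
        # evaluate in groups bounded by total pair count so large meshes
        # with distant query points stay within memory
        budget = 2_000_000
        start = 0
        n = len(points)
        while start < n:
            stop = start
            total = 0
            while stop < n and (total + counts[stop] <= budget or stop == start):
                total += counts[stop]
                stop += 1
            if total:
                idx = np.concatenate(
                    [np.asarray(lists[i], dtype=np.int64) for i in range(start, stop)]
                )
                c = counts[start:stop]
                flat_pts = np.repeat(points[start:stop], c, axis=0)
                d2 = _closest_point_on_triangles(flat_pts, self._tri[idx])
                np.minimum.at(
                    out,
                    np.repeat(np.arange(start, stop), c),
                    np.sqrt(d2),
                )
            start = stop
        return out


def surface_distance(points: np.ndarray, meshes: list[SurfaceMesh]) -> np.ndarray:
    """Distance from points to the nearest surface among several meshes."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    out = np.full(len(points), np.inf)
    for m in meshes:
        if m.is_empty:
            continue
        out = np.minimum(out, MeshDistanceQuery(m).distances(points))
    return out


# ---------------------------------------------------------------------------
# Segment / triangle intersection and segment / segment distance
# ---------------------------------------------------------------------------

def segment_intersects_mesh(p0: np.ndarray, p1: np.ndarray, mesh: SurfaceMesh) -> bool:
    """Moller-Trumbore segment/triangle test against every face."""
    if mesh.is_empty:
        return False
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = p1 - p0
    tri = mesh.triangles()
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    h = np.cross(d[None, :], e2)
    a = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(a) > 1e-12
    if not ok.any():
        return False
    f = np.zeros_like(a)
    f[ok] = 1.0 / a[ok]
    s = p0[None, :] - tri[:, 0]
    u = f * np.einsum("ij,ij->i", s, h)
    q = np.cross(s, e1)
    v = f * np.einsum("j,ij->i", d, q)
    t = f * np.einsum("ij,ij->i", e2, q)
    hit = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t >= 0) & (t <= 1)
    return bool(hit.any())


def segment_segment_distance(
    p1: np.ndarray, q1: np.ndarray, p2: np.ndarray, q2: np.ndarray
) -> float:
    """Minimum distance between segments [p1,q1] and [p2,q2]."""
    p1, q1, p2, q2 = (np.asarray(x, dtype=float) for x in (p1, q1, p2, q2))
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = d1 @ d1
    e = d2 @ d2
    f = d2 @ r
    if a <= 1e-15 and e <= 1e-15:
        return float(np.linalg.norm(r))
    if a <= 1e-15:
        s, t = 0.0, np.clip(f / e, 0.0, 1.0)
    else:
        c = d1 @ r
        if e <= 1e-15:
            t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
        else:
            b = d1 @ d2
            denom = a * e - b * b
            s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > 1e-15 else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
            elif t > 1.0:
                t, s = 1.0, np.clip((b - c) / a, 0.0, 1.0)
    c1 = p1 + s * d1
    c2 = p2 + t * d2
    return float(np.linalg.norm(c1 - c2))


def segment_segment_distance_matrix(
    p1: np.ndarray, q1: np.ndarray, p2: np.ndarray, q2: np.ndarray
) -> np.ndarray:
    """Pairwise minimum distances between two families of 3-D segments.

    ``p1, q1``: (n, 3) endpoints; ``p2, q2``: (m, 3).  Returns (n, m).
    Vectorised form of the clamped closest-point algorithm used by
    :func:`segment_segment_distance`.
    """
    p1 = np.atleast_2d(p1)[:, None, :]
    q1 = np.atleast_2d(q1)[:, None, :]
    p2 = np.atleast_2d(p2)[None, :, :]
    q2 = np.atleast_2d(q2)[None, :, :]
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = np.einsum("...k,...k->...", d1, d1)
    e = np.einsum("...k,...k->...", d2, d2)
    f = np.einsum("...k,...k->...", d2, r)
    c = np.einsum("...k,...k->...", d1, r)
    b = np.einsum("...k,...k->...", d1, d2)
    denom = a * e - b * b
    s = np.where(denom > 1e-15, np.clip((b * f - c * e) / np.where(denom > 1e-15, denom, 1.0), 0, 1), 0.0)
    # handle degenerate segments
    a_ok = a > 1e-15
    e_ok = e > 1e-15
    t = np.where(e_ok, (b * s + f) / np.where(e_ok, e, 1.0), 0.0)
    t_low = t < 0.0
    t_high = t > 1.0
    s = np.where(t_low & a_ok, np.clip(-c / np.where(a_ok, a, 1.0), 0, 1), s)
    s = np.where(t_high & a_ok, np.clip((b - c) / np.where(a_ok, a, 1.0), 0, 1), s)
    s = np.where(a_ok, s, 0.0)
    t = np.clip(t, 0.0, 1.0)
    t = np.where(e_ok, t, 0.0)
    c1 = p1 + s[..., None] * d1
    c2 = p2 + t[..., None] * d2
    return np.linalg.norm(c1 - c2, axis=-1)


# ---------------------------------------------------------------------------
# Voxelisation of a closed surface
# ---------------------------------------------------------------------------

def voxelize_closed_mesh(mesh: SurfaceMesh, grid: Grid) -> np.ndarray:
    """Binary occupancy (surface + interior) of a closed mesh on ``grid``.

    Surface voxels are marked by recursive triangle subdivision down to
    sub-voxel edge length; the exterior is then flood-filled from the volume
    border and everything unreached is interior.  Raises if the mesh is too
    thin to occupy a single voxel.
    """
    if mesh.is_empty:
        raise ValueError("cannot voxelize an empty mesh")
    min_sp = min(grid.spacing)
    tris = [mesh.triangles()]
    surface_pts = []
    while tris:
        t = tris.pop()
        edge = np.linalg.norm(
            t - np.roll(t, 1, axis=1), axis=2
        ).max(axis=1)
        fine = edge <= 0.5 * min_sp
        surface_pts.append(t[fine].reshape(-1, 3))
        coarse = t[~fine]
        if len(coarse):
            a, b, c = coarse[:, 0], coarse[:, 1], coarse[:, 2]
            ab = 0.5 * (a + b)
            bc = 0.5 * (b + c)
            ca = 0.5 * (c + a)
            tris.append(
                np.concatenate(
                    [
                        np.stack([a, ab, ca], axis=1),
                        np.stack([ab, b, bc], axis=1),
                        np.stack([ca, bc, c], axis=1),
                        np.stack([ab, bc, ca], axis=1),
                    ]
                )
            )
    pts = np.vstack(surface_pts)
    vox = np.rint(grid.world_to_voxel(pts)).astype(int)
    inside = np.all((vox >= 0) & (vox < np.array(grid.shape)), axis=1)
    vox = vox[inside]
    if len(vox) == 0:
        raise ValueError("mesh does not intersect the grid; use a finer grid")
    surface = np.zeros(grid.shape, dtype=bool)
    surface[vox[:, 0], vox[:, 1], vox[:, 2]] = True

    open_space = ~surface
    labels, _ = ndimage.label(open_space)
    border_labels = np.unique(
        np.concatenate(
            [
                labels[0].ravel(), labels[-1].ravel(),
                labels[:, 0].ravel(), labels[:, -1].ravel(),
                labels[:, :, 0].ravel(), labels[:, :, -1].ravel(),
            ]
        )
    )
    border_labels = border_labels[border_labels != 0]
    exterior = np.isin(labels, border_labels)
    filled = ~exterior
    if filled.sum() <= surface.sum():
        # no interior voxels at all -> thinner than one voxel everywhere
        if not filled.any():
            raise ValueError("mesh thinner than one voxel; use a finer grid")
    return filled
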