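"""Seeded head phantoms with a ground-truth vascular tree.

The phantom stands in for the study's imaging data: one branching vascular
tree (the truth) rendered as three modality volumes which differ in the
smallest vessel diameter they reveal, plus an intracranial mask, a
gray-matter ribbon with sulcal infoldings, a skull shell and deep target
regions.  The gold-standard modality shows every vessel; the degraded
modalities hide vessels thinner than 2 mm and 4 mm respectively, emulating
the resolution gap between catheter angiography and MR-based vascular
imaging.

Every quantity is derived from a single integer seed, so identical
(seed, config) pairs yield bit-identical phantoms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .grids import Grid
from .mesh import SurfaceMesh, concatenate_meshes
from .registration import AffineTransform, resample_volume


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class VascularTree:
    """Branching tube geometry with per-segment radii (phantom ground truth).

    ``starts[i] -> ends[i]`` is segment i with radius ``radii[i]`` (mm);
    ``parents[i]`` is the parent segment index or -1 for a root.  Segments
    form a forest and child radii never exceed the parent's.
    """

    starts: np.ndarray
    ends: np.ndarray
    radii: np.ndarray
    parents: np.ndarray
    roots: np.ndarray  # (k, 3) root points

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=float).reshape(-1, 3)
        self.ends = np.asarray(self.ends, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float).ravel()
        self.parents = np.asarray(self.parents, dtype=np.int64).ravel()
        self.roots = np.asarray(self.roots, dtype=float).reshape(-1, 3)
        n = len(self.radii)
        if not (len(self.starts) == len(self.ends) == len(self.parents) == n):
            raise ValueError("inconsistent segment arrays")
        if n and self.radii.min() <= 0:
            raise ValueError("segment radii must be positive")

    @property
    def n_segments(self) -> int:
        return len(self.radii)

    @property
    def diameters(self) -> np.ndarray:
        return 2.0 * self.radii

    def subset(self, keep: np.ndarray) -> "VascularTree":
        """Sub-forest of flagged segments (parents outside become roots)."""
        keep = np.asarray(keep, dtype=bool)
        idx = np.flatnonzero(keep)
        remap = -np.ones(self.n_segments, dtype=np.int64)
        remap[idx] = np.arange(len(idx))
        parents = np.array(
            [remap[p] if p >= 0 and keep[p] else -1 for p in self.parents[idx]],
            dtype=np.int64,
        )
        return VascularTree(
            self.starts[idx], self.ends[idx], self.radii[idx], parents, self.roots
        )

    def visible(self, min_diameter: float) -> "VascularTree":
        """Segments a modality with the given diameter floor reveals."""
        return self.subset(self.diameters >= min_diameter)

    def nearest_segment(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(segment index, axis distance) of the nearest segment per point.

        This is the ground-truth oracle: for a rendered voxel it recovers
        the generating segment and hence its true diameter.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if self.n_segments == 0:
            return (np.full(len(points), -1), np.full(len(points), np.inf))
        best_d = np.full(len(points), np.inf)
        best_i = np.full(len(points), -1, dtype=np.int64)
        for i in range(self.n_segments):
            d = _point_segment_distance(points, self.starts[i], self.ends[i])
            better = d < best_d
            best_d[better] = d[better]
            best_i[better] = i
        return best_i, best_d

    def surface_distance(self, points: np.ndarray) -> np.ndarray:
        """Exact distance from points to the union-of-tubes surface
        (negative inside a tube)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if self.n_segments == 0:
            return np.full(len(points), np.inf)
        best = np.full(len(points), np.inf)
        for i in range(self.n_segments):
            d = _point_segment_distance(points, self.starts[i], self.ends[i])
            best = np.minimum(best, d - self.radii[i])
        return best

    def segment_label_volume(self, grid: Grid, min_diameter: float = 0.0) -> np.ndarray:
        """Per-voxel generating-segment index (-1 outside every tube)."""
        labels = np.full(grid.shape, -1, dtype=np.int64)
        order = np.argsort(self.radii)  # thicker segments win ties (drawn last)
        for i in order:
            if self.diameters[i] < min_diameter:
                continue
            _paint_tube(labels, grid, self.starts[i], self.ends[i], self.radii[i], i)
        return labels

    # -- serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "starts": self.starts.tolist(),
            "ends": self.ends.tolist(),
            "radii": self.radii.tolist(),
            "parents": self.parents.tolist(),
            "roots": self.roots.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VascularTree":
        return cls(
            np.asarray(d["starts"]), np.asarray(d["ends"]),
            np.asarray(d["radii"]), np.asarray(d["parents"]),
            np.asarray(d["roots"]),
        )


@dataclass(frozen=True)
class ModalityProfile:
    """How a vascular imaging modality degrades the true tree.

    ``min_visible_diameter`` is the smallest vessel diameter (mm) the
    modality resolves at all; thinner segments contribute nothing to the
    rendered volume.  Blur approximates partial-volume averaging and noise
    is additive Gaussian.
    """

    name: str
    min_visible_diameter: float = 0.0
    blur_sigma: float = 0.5
    noise_sd: float = 0.02
    contrast: float = 1.0

    def __post_init__(self) -> None:
        bad = []
        if self.min_visible_diameter < 0:
            bad.append("min_visible_diameter")
        if self.blur_sigma < 0:
            bad.append("blur_sigma")
        if self.noise_sd < 0:
            bad.append("noise_sd")
        if bad:
            raise ValueError(f"negative modality parameters: {bad}")


# the three fidelities differ only in the smallest diameter they reveal;
# blur (0.5 voxel partial-volume proxy), noise and contrast are common so
# that relative detectability is the only degradation under study
DEFAULT_PROFILES = (
    ModalityProfile("gold", 0.0, 0.5, 0.02, 1.0),
    ModalityProfile("mid", 2.0, 0.5, 0.02, 1.0),
    ModalityProfile("low", 4.0, 0.5, 0.02, 1.0),
)


@dataclass
class BranchParams:
    """Recursive-bifurcation settings for the tree generator.

    Each child's radius is its parent's times ``radius_decay`` plus a
    uniform jitter of ``radius_decay_jitter``, from ``root_radius`` down to
    ``min_radius``; the jitter keeps the caliber distribution continuous.
    With the defaults the radii span about 0.4-4.0 mm, so every pruning
    threshold in {1, 2, 3, 4} mm diameter is informative.
    """

    root_radius: float = 4.0
    radius_decay: float = 0.75
    radius_decay_jitter: float = 0.08  # uniform half-width around the decay
    segment_length: tuple[float, float] = (6.0, 12.0)
    bifurcation_prob: float = 0.65
    branch_angle_deg: tuple[float, float] = (20.0, 40.0)
    direction_jitter_deg: float = 12.0
    max_generations: int = 8
    min_radius: float = 0.35
    max_retries: int = 25


@dataclass
class PhantomConfig:
    """Study-scale phantom settings (desk-scale head on a 96^3 mm grid)."""

    grid: Grid = field(default_factory=Grid)
    icv_radius: float = 40.0
    skull_thickness: float = 3.0
    gm_thickness: float = 3.0
    n_sulci: int = 6
    sulcus_depth: float = 15.0
    sulcus_half_width: float = 1.5
    sulcus_half_extent: float = 12.0
    n_target_rois: int = 8
    roi_radius: float = 5.0
    roi_shell_radius: float = 24.0
    roi_min_vessel_clearance: float = 6.0
    roi_min_separation: float = 18.0
    n_roots: int = 2
    branch: BranchParams = field(default_factory=BranchParams)
    profiles: tuple[ModalityProfile, ...] = DEFAULT_PROFILES
    misalign: bool = False
    max_misalign_translation_vox: float = 3.0
    max_misalign_rotation_deg: float = 2.0

    def validate(self) -> None:
        problems = []
        if self.n_target_rois < 1:
            problems.append("n_target_rois must be >= 1")
        if len(self.profiles) < 1:
            problems.append("at least one modality profile required")
        names = [p.name for p in self.profiles]
        if len(set(names)) != len(names):
            problems.append("modality profile names must be unique")
        if self.icv_radius + self.skull_thickness > min(
            -self.grid.origin[a] for a in range(3)
        ):
            problems.append("skull does not fit inside the grid")
        if self.roi_shell_radius + self.roi_radius >= self.icv_radius:
            problems.append("target ROIs would leave the intracranial mask")
        if problems:
            raise ValueError("; ".join(problems))


@dataclass
class Phantom:
    """Complete synthetic head: masks, meshes, truth tree, modality images."""

    grid: Grid
    intracranial_mask: np.ndarray
    gm_mask: np.ndarray
    skull_mesh: SurfaceMesh
    target_rois: np.ndarray
    tree: VascularTree
    modality_images: dict[str, np.ndarray]
    true_transforms: dict[str, AffineTransform]
    config: PhantomConfig
    seed: int

    def roi_labels(self) -> np.ndarray:
        labs = np.unique(self.target_rois)
        return labs[labs > 0]


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _point_segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    denom = float(ab @ ab)
    if denom < 1e-15:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def _tube_bbox_slices(grid: Grid, a: np.ndarray, b: np.ndarray, r: float, pad: float = 1.0):
    lo = np.minimum(a, b) - (r + pad)
    hi = np.maximum(a, b) + (r + pad)
    vlo = np.floor(grid.world_to_voxel(lo)).astype(int)
    vhi = np.ceil(grid.world_to_voxel(hi)).astype(int) + 1
    vlo = np.clip(vlo, 0, np.array(grid.shape))
    vhi = np.clip(vhi, 0, np.array(grid.shape))
    if np.any(vlo >= vhi):
        return None, None
    slices = tuple(slice(vlo[a_], vhi[a_]) for a_ in range(3))
    axes = [
        grid.origin[a_] + (np.arange(vlo[a_], vhi[a_]) + 0.5) * grid.spacing[a_]
        for a_ in range(3)
    ]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    return slices, pts


def _paint_tube(vol: np.ndarray, grid: Grid, a, b, r: float, value) -> None:
    slices, pts = _tube_bbox_slices(grid, np.asarray(a), np.asarray(b), r)
    if slices is None:
        return
    d = _point_segment_distance(pts.reshape(-1, 3), np.asarray(a), np.asarray(b))
    inside = (d <= r).reshape(pts.shape[:3])
    vol[slices][inside] = value


def tube_mask(tree: VascularTree, grid: Grid, min_diameter: float = 0.0) -> np.ndarray:
    """Analytic binary occupancy of all segments at/above a diameter floor."""
    out = np.zeros(grid.shape, dtype=bool)
    for i in range(tree.n_segments):
        if tree.diameters[i] >= min_diameter:
            _paint_tube(out, grid, tree.starts[i], tree.ends[i], tree.radii[i], True)
    return out


def _cylinder_mesh(
    a: np.ndarray, b: np.ndarray, r: float, n_theta: int = 12,
    max_ring_spacing: float = 3.0,
) -> SurfaceMesh:
    """Closed cylinder from a to b with per-vertex radius r.

    Rings are placed at most ``max_ring_spacing`` mm apart so that no
    triangle spans the whole segment (keeps spatial culling in distance
    queries effective).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    axis = b - a
    length = np.linalg.norm(axis)
    if length < 1e-12:
        axis = np.array([0.0, 0.0, 1.0])
    else:
        axis = axis / length
    ref = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    ring = np.cos(theta)[:, None] * u + np.sin(theta)[:, None] * v

    n_axial = max(1, int(np.ceil(length / max_ring_spacing)))
    ring_centers = a + np.linspace(0, 1, n_axial + 1)[:, None] * (b - a)
    rings = ring_centers[:, None, :] + r * ring[None, :, :]   # (n_axial+1, n_theta, 3)
    verts = np.vstack([rings.reshape(-1, 3), a[None, :], b[None, :]])
    ca, cb = (n_axial + 1) * n_theta, (n_axial + 1) * n_theta + 1
    faces = []
    for k in range(n_axial):
        base0 = k * n_theta
        base1 = (k + 1) * n_theta
        for i in range(n_theta):
            j = (i + 1) % n_theta
            faces.append([base0 + i, base0 + j, base1 + i])
            faces.append([base0 + j, base1 + j, base1 + i])
    last = n_axial * n_theta
    for i in range(n_theta):
        j = (i + 1) % n_theta
        faces.append([ca, j, i])               # cap at a
        faces.append([cb, last + i, last + j])  # cap at b
    rad = np.full(len(verts), r)
    return SurfaceMesh(verts, np.asarray(faces), rad)


def transform_tree(tree: VascularTree, t: AffineTransform) -> VascularTree:
    """Map segment endpoints through an affine; radii scale by the mean
    scale factor (matching the mesh-transform convention)."""
    s = float(np.mean(t.scale))
    return VascularTree(
        t.apply_points(tree.starts) if tree.n_segments else tree.starts,
        t.apply_points(tree.ends) if tree.n_segments else tree.ends,
        tree.radii * s,
        tree.parents,
        t.apply_points(tree.roots) if len(tree.roots) else tree.roots,
    )


def tree_to_mesh(
    tree: VascularTree, min_diameter: float = 0.0, n_theta: int = 12
) -> SurfaceMesh:
    """Analytic tube mesh of the (visibility-filtered) tree.

    Per-vertex radii carry the true segment radius, so diameter pruning on
    this mesh removes exactly the thin segments — the geometric ground
    truth against which image-derived models are compared.
    """
    parts = [
        _cylinder_mesh(tree.starts[i], tree.ends[i], tree.radii[i], n_theta)
        for i in range(tree.n_segments)
        if tree.diameters[i] >= min_diameter
    ]
    return concatenate_meshes(parts)


# ---------------------------------------------------------------------------
# Tree growth
# ---------------------------------------------------------------------------

def _jitter_direction(rng: np.random.Generator, d: np.ndarray, max_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis -= (axis @ d) * d
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        return d
    axis /= norm
    ang = np.deg2rad(rng.uniform(0, max_deg))
    return _rotate_about(d, axis, ang)


def _rotate_about(v: np.ndarray, axis: np.ndarray, ang: float) -> np.ndarray:
    return (
        v * np.cos(ang)
        + np.cross(axis, v) * np.sin(ang)
        + axis * (axis @ v) * (1 - np.cos(ang))
    )


def grow_vascular_tree(
    seed: int,
    domain: np.ndarray,
    grid: Grid,
    n_roots: int = 2,
    branch_params: BranchParams | None = None,
) -> VascularTree:
    """Grow a random bifurcating tree confined to a binary domain.

    Recursive bifurcation with jittered directions; each child's radius
    decays by a randomised factor (``radius_decay`` +- its jitter), giving
    a continuous caliber distribution rather than discrete generation
    steps (no hemodynamic model).  Segment endpoints
    and midpoints must land inside ``domain``; a candidate direction is
    re-drawn up to ``max_retries`` times before the branch is abandoned.
    Raises if the domain is empty or no root segment can be confined.
    """
    domain = np.asarray(domain, dtype=bool)
    if not domain.any():
        raise ValueError("empty domain for vascular-tree growth")
    params = branch_params or BranchParams()
    rng = np.random.default_rng(seed)

    if n_roots == 0:
        return VascularTree(
            np.zeros((0, 3)), np.zeros((0, 3)), np.zeros(0),
            np.zeros(0, dtype=np.int64), np.zeros((0, 3)),
        )

    centroid = grid.voxel_to_world(
        np.array(np.nonzero(domain)).mean(axis=1)
    )
    dom_idx = np.array(np.nonzero(domain)).T
    dom_pts = grid.voxel_to_world(dom_idx)
    radial = np.linalg.norm(dom_pts - centroid, axis=1)
    outer = dom_pts[radial >= np.quantile(radial, 0.9)]

    starts: list[np.ndarray] = []
    ends: list[np.ndarray] = []
    radii: list[float] = []
    parents: list[int] = []
    root_pts: list[np.ndarray] = []

    def inside(p: np.ndarray) -> bool:
        return bool(grid.contains_points(domain, p[None, :])[0])

    def child_radius(parent_r: float) -> float:
        decay = params.radius_decay + rng.uniform(
            -params.radius_decay_jitter, params.radius_decay_jitter
        )
        return parent_r * min(decay, 1.0)

    # FIFO queue keeps growth order deterministic
    queue: list[tuple[np.ndarray, np.ndarray, float, int, int]] = []
    for _ in range(n_roots):
        root = outer[rng.integers(len(outer))]
        d = centroid - root
        d = d / np.linalg.norm(d)
        queue.append((root.copy(), d, params.root_radius, 0, -1))
        root_pts.append(root.copy())

    while queue:
        start, direction, radius, gen, parent = queue.pop(0)
        if radius < params.min_radius or gen > params.max_generations:
            continue
        placed = False
        for _ in range(params.max_retries):
            d = _jitter_direction(rng, direction, params.direction_jitter_deg)
            length = rng.uniform(*params.segment_length)
            end = start + d * length
            if inside(end) and inside(0.5 * (start + end)):
                placed = True
                break
        if not placed:
            continue
        starts.append(start)
        ends.append(end)
        radii.append(radius)
        parents.append(parent)
        my_idx = len(radii) - 1

        if rng.random() < params.bifurcation_prob:
            half = 0.5 * np.deg2rad(rng.uniform(*params.branch_angle_deg))
            axis = rng.normal(size=3)
            axis -= (axis @ d) * d
            axis /= max(np.linalg.norm(axis), 1e-12)
            d1 = _rotate_about(d, axis, half)
            d2 = _rotate_about(d, axis, -half)
            queue.append((end.copy(), d1, child_radius(radius), gen + 1, my_idx))
            queue.append((end.copy(), d2, child_radius(radius), gen + 1, my_idx))
        else:
            queue.append((end.copy(), d, child_radius(radius), gen + 1, my_idx))

    if not radii:
        raise ValueError(
            f"could not confine any root segment to the domain (seed={seed})"
        )
    return VascularTree(
        np.asarray(starts), np.asarray(ends), np.asarray(radii),
        np.asarray(parents, dtype=np.int64), np.asarray(root_pts),
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_modality(
    tree: VascularTree,
    profile: ModalityProfile,
    grid: Grid,
    seed: int,
    misalign: AffineTransform | None = None,
) -> np.ndarray:
    """Render the tree as one modality volume.

    Segments with diameter >= the modality's visibility floor are painted
    at ``contrast``; Gaussian blur (partial volume) and additive Gaussian
    noise follow.  ``misalign``, when given, resamples the clean tube image
    through the transform before blur/noise, emulating an acquisition in a
    different frame (the true transform is the caller's to keep).
    """
    rendered = tree.radii[tree.diameters >= profile.min_visible_diameter]
    if len(rendered) and min(grid.spacing) > rendered.min():
        warnings.warn(
            "voxel size exceeds the smallest rendered vessel radius; "
            "thin vessels will be poorly sampled"
        )
    img = np.zeros(grid.shape, dtype=float)
    for i in range(tree.n_segments):
        if tree.diameters[i] >= profile.min_visible_diameter:
            _paint_tube(
                img, grid, tree.starts[i], tree.ends[i], tree.radii[i],
                profile.contrast,
            )
    if misalign is not None:
        img = resample_volume(img, grid, misalign, cval=0.0)
    if profile.blur_sigma > 0:
        img = ndimage.gaussian_filter(
            img, [profile.blur_sigma / s for s in grid.spacing]
        )
    if profile.noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, profile.noise_sd, size=img.shape)
    return img


# ---------------------------------------------------------------------------
# Phantom assembly
# ---------------------------------------------------------------------------

def _ball_mask(grid: Grid, center: np.ndarray, radius: float) -> np.ndarray:
    pts = grid.voxel_centers()
    return np.linalg.norm(pts - center, axis=-1) <= radius


def _fibonacci_directions(n: int) -> np.ndarray:
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0))
    y = 1 - 2 * (i + 0.5) / n
    r = np.sqrt(1 - y * y)
    return np.stack([r * np.cos(phi * i), y, r * np.sin(phi * i)], axis=1)


def _mesh_from_mask(mask: np.ndarray, grid: Grid, level: float = 0.5) -> SurfaceMesh:
    verts, faces, _, _ = measure.marching_cubes(mask.astype(float), level=level)
    verts_mm = grid.voxel_to_world(verts)
    return SurfaceMesh(verts_mm, faces)


def make_phantom(seed: int, config: PhantomConfig | None = None) -> Phantom:
    """Assemble the full synthetic head for one seed.

    The seed drives the tree, the sulcal fold placement jitter, the ROI
    jitter, the per-modality noise and (optionally) the per-modality
    misalignment; mask construction parameters come from the config alone,
    so two seeds differ only where randomness is intended.
    """
    config = config or PhantomConfig()
    config.validate()
    grid = config.grid
    rng = np.random.default_rng(seed)
    center = np.zeros(3)

    pts = grid.voxel_centers()
    r = np.linalg.norm(pts - center, axis=-1)
    icv = r <= config.icv_radius
    skull_outer = config.icv_radius + config.skull_thickness
    skull_mask = (r > config.icv_radius) & (r <= skull_outer)
    skull_mesh = _mesh_from_mask(r <= skull_outer, grid)

    # cortical ribbon + sulcal infoldings
    gm = icv & (r >= config.icv_radius - config.gm_thickness)
    fold_dirs = _fibonacci_directions(max(config.n_sulci, 1))
    for k in range(config.n_sulci):
        u = fold_dirs[k] + rng.normal(0, 0.08, 3)
        u /= np.linalg.norm(u)
        surf_pt = center + u * config.icv_radius
        n_vec = rng.normal(size=3)
        n_vec -= (n_vec @ u) * u
        n_vec /= np.linalg.norm(n_vec)
        rel = pts - surf_pt
        depth_coord = -(rel @ u)          # >0 going inward
        plane_dist = np.abs(rel @ n_vec)
        lateral = np.linalg.norm(
            rel - (rel @ u)[..., None] * u - (rel @ n_vec)[..., None] * n_vec,
            axis=-1,
        )
        fold = (
            (plane_dist <= config.sulcus_half_width)
            & (depth_coord >= 0)
            & (depth_coord <= config.sulcus_depth)
            & (lateral <= config.sulcus_half_extent)
            & icv
        )
        gm |= fold

    # vascular tree confined well inside the intracranial space; the growth
    # domain is discretised on a fixed canonical lattice so the truth tree
    # does not depend on the rendering grid
    dom_grid = Grid(
        (96, 96, 96), (1.0, 1.0, 1.0),
        (-48.0, -48.0, -48.0),
    )
    dom_r = np.linalg.norm(dom_grid.voxel_centers() - center, axis=-1)
    margin = config.branch.root_radius + 1.5
    domain = dom_r <= config.icv_radius - margin
    tree = grow_vascular_tree(seed, domain, dom_grid, config.n_roots, config.branch)

    # deep target ROIs (gray-matter nuclei adjacent to the folds); centres
    # are re-jittered away from vessels so every target is implantable
    rois = np.zeros(grid.shape, dtype=np.int16)
    roi_dirs = _fibonacci_directions(config.n_target_rois)
    clearance = config.roi_min_vessel_clearance
    placed: list[np.ndarray] = []
    for k in range(config.n_target_rois):
        c = roi_dirs[k] * config.roi_shell_radius + rng.normal(0, 1.5, 3)
        for attempt in range(80):
            clear = tree.surface_distance(c[None, :])[0] >= clearance
            apart = all(
                np.linalg.norm(c - p) >= config.roi_min_separation for p in placed
            )
            if clear and apart:
                break
            sd = 1.5 + 0.1 * attempt
            c = roi_dirs[k] * config.roi_shell_radius + rng.normal(0, sd, 3)
        placed.append(c)
        ball = _ball_mask(grid, c, config.roi_radius) & icv
        rois[ball & (rois == 0)] = k + 1
    gm |= rois > 0
    gm &= icv

    images: dict[str, np.ndarray] = {}
    transforms: dict[str, AffineTransform] = {}
    child = np.random.default_rng(seed).spawn(len(config.profiles) * 2)
    g_center = tuple(grid.voxel_to_world(np.array(grid.shape) / 2.0 - 0.5))
    for j, prof in enumerate(config.profiles):
        t = AffineTransform(center_mm=g_center)
        if config.misalign and prof.min_visible_diameter > 0:
            mis_rng = child[2 * j]
            t = AffineTransform(
                rotation_deg=tuple(
                    mis_rng.uniform(-1, 1, 3) * config.max_misalign_rotation_deg
                ),
                translation_mm=tuple(
                    mis_rng.uniform(-1, 1, 3)
                    * config.max_misalign_translation_vox
                    * min(grid.spacing)
                ),
                center_mm=g_center,
            )
        noise_seed = int(child[2 * j + 1].integers(2**31 - 1))
        images[prof.name] = render_modality(
            tree, prof, grid, noise_seed,
            misalign=None if not config.misalign or prof.min_visible_diameter == 0 else t,
        )
        transforms[prof.name] = t

    return Phantom(
        grid=grid,
        intracranial_mask=icv,
        gm_mask=gm,
        skull_mesh=skull_mesh,
        target_rois=rois,
        tree=tree,
        modality_images=images,
        true_transforms=transforms,
        config=config,
        seed=seed,
    )
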