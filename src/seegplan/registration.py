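"""Affine co-registration of modality volumes by normalised mutual information.

The reference frame is the gold-standard (contrast-MR-like) image; each
floating modality image is brought into it with a nine-parameter affine
(three rotations, three translations, three independent scales), found by
maximising normalised mutual information (NMI) over a two-level image
pyramid with derivative-free (Nelder--Mead) optimisation.

NMI here is the Studholme form ``(H(A) + H(B)) / H(A, B)`` computed from a
joint histogram over the voxels where the resampled floating image is
defined; it is >= 1 and invariant to bijective intensity remappings at the
histogram level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .grids import Grid
from .mesh import SurfaceMesh


@dataclass
class AffineTransform:
    """Rotation (degrees, intrinsic xyz), translation (mm), per-axis scale.

    The linear part acts about ``center_mm`` so small rotations of a
    head-centred volume do not translate it off the grid.  Composes to a
    4x4 homogeneous world->world matrix as ``T(c) Rz Ry Rx S T(-c) + t``.
    ``matrix_override``, when set, supplies the matrix directly (used for
    exact inverses of anisotropic transforms).
    """

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scale: tuple[float, float, float] = (1.0, 1.0, 1.0)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    matrix_override: np.ndarray | None = None

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.scale):
            raise ValueError("scale factors must be positive")

    @property
    def matrix(self) -> np.ndarray:
        if self.matrix_override is not None:
            return np.asarray(self.matrix_override, dtype=float)
        rx, ry, rz = np.deg2rad(self.rotation_deg)
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        lin = Rz @ Ry @ Rx @ np.diag(self.scale)
        c = np.asarray(self.center_mm, dtype=float)
        t = np.asarray(self.translation_mm, dtype=float)
        mat = np.eye(4)
        mat[:3, :3] = lin
        mat[:3, 3] = c - lin @ c + t
        return mat

    def apply_points(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        return xyz @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def inverse(self) -> "AffineTransform":
        """Exact inverse (matrix level); mean radius scale is 1/mean handled
        by storing the reciprocal scales."""
        inv = np.linalg.inv(self.matrix)
        s = tuple(1.0 / np.asarray(self.scale, dtype=float))
        return AffineTransform(
            rotation_deg=tuple(-np.asarray(self.rotation_deg)),
            translation_mm=tuple(-np.asarray(self.translation_mm)),
            scale=s,
            center_mm=self.center_mm,
            matrix_override=inv,
        )

    @property
    def params(self) -> np.ndarray:
        return np.concatenate(
            [self.translation_mm, self.rotation_deg, self.scale]
        ).astype(float)

    @classmethod
    def from_params(cls, p: np.ndarray, center_mm=(0.0, 0.0, 0.0)) -> "AffineTransform":
        p = np.asarray(p, dtype=float)
        return cls(
            rotation_deg=tuple(p[3:6]),
            translation_mm=tuple(p[0:3]),
            scale=tuple(p[6:9]),
            center_mm=tuple(center_mm),
        )

    def to_dict(self) -> dict:
        return {
            "rotation_deg": list(self.rotation_deg),
            "translation_mm": list(self.translation_mm),
            "scale": list(self.scale),
            "center_mm": list(self.center_mm),
            "matrix": self.matrix.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform":
        return cls(
            tuple(d["rotation_deg"]),
            tuple(d["translation_mm"]),
            tuple(d["scale"]),
            tuple(d.get("center_mm", (0.0, 0.0, 0.0))),
        )


def resample_volume(
    moving: np.ndarray,
    grid: Grid,
    transform: AffineTransform,
    order: int = 1,
    cval: float = np.nan,
    out_grid: Grid | None = None,
) -> np.ndarray:
    """Resample ``moving`` into the fixed frame under a world transform.

    Each output voxel centre (on ``out_grid``, default the moving grid)
    maps to world coordinates, then through the inverse world transform
    into the moving volume; out-of-volume samples become ``cval`` (NaN by
    default so overlap masks are explicit).
    """
    out_grid = out_grid or grid
    inv = transform.inverse().matrix
    sp_in = grid.spacing_arr
    org_in = grid.origin_arr + 0.5 * sp_in
    sp_out = out_grid.spacing_arr
    org_out = out_grid.origin_arr + 0.5 * sp_out
    Avox = (inv[:3, :3] * sp_out[None, :]) / sp_in[:, None]
    b = (inv[:3, :3] @ org_out + inv[:3, 3] - org_in) / sp_in
    return ndimage.affine_transform(
        np.asarray(moving, dtype=float),
        Avox,
        offset=b,
        output_shape=out_grid.shape,
        order=order,
        mode="constant",
        cval=cval,
        prefilter=order > 1,
    )


def normalized_mutual_information(
    fixed: np.ndarray, moving: np.ndarray, bins: int = 64
) -> float:
    """Studholme NMI over voxels where both volumes are finite; >= 1."""
    if bins < 2:
        raise ValueError("bins must be >= 2")
    a = np.asarray(fixed, dtype=float).ravel()
    b = np.asarray(moving, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("fixed and moving must share a grid")
    ok = np.isfinite(a) & np.isfinite(b)
    if not ok.any():
        raise ValueError("empty overlap between fixed and moving volumes")
    hist, _, _ = np.histogram2d(a[ok], b[ok], bins=bins)
    p = hist / hist.sum()

    def entropy(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    hab = entropy(p.ravel())
    if hab == 0.0:
        return 2.0
    return (entropy(p.sum(axis=1)) + entropy(p.sum(axis=0))) / hab


def _downsample(vol: np.ndarray) -> np.ndarray:
    return ndimage.gaussian_filter(np.asarray(vol, dtype=float), 2.0)[::2, ::2, ::2]


def register_affine_nmi(
    fixed: np.ndarray,
    grid: Grid,
    moving: np.ndarray,
    init: AffineTransform | None = None,
    bins: int = 128,
    n_starts: int = 3,
    seed: int = 0,
    maxiter: int = 500,
) -> AffineTransform:
    """Recover the affine mapping ``moving`` onto ``fixed`` by maximising NMI.

    Two-level pyramid, Nelder--Mead at each level.  If the first start does
    not improve on ``init``, additional seeded restarts perturb the initial
    parameters; if nothing improves, ``init`` is returned with a warning.
    """
    center = tuple(grid.voxel_to_world(np.array(grid.shape) / 2.0 - 0.5))
    if init is None:
        init = AffineTransform(center_mm=center)
    rng = np.random.default_rng(seed)

    grid_half = Grid(
        tuple(s // 2 for s in grid.shape),
        tuple(s * 2 for s in grid.spacing),
        grid.origin,
    )
    # The metric is evaluated on mildly smoothed volumes and on a probe
    # lattice offset by an irrational-ish fraction of a voxel.  Both fight
    # the interpolation artifact: with sharp images sampled on the native
    # lattice, NMI rewards transforms whose sampling positions align with
    # the moving grid (e.g. a unit scale factor) over true alignment; an
    # off-lattice probe denies every candidate that advantage.
    fixed_s = ndimage.gaussian_filter(np.asarray(fixed, float), 1.0)
    moving_s = ndimage.gaussian_filter(np.asarray(moving, float), 1.0)
    delta = 0.37
    probe_fine = Grid(
        tuple(s - 1 for s in grid.shape),
        grid.spacing,
        tuple(o + delta * sp for o, sp in zip(grid.origin, grid.spacing)),
    )
    probe_half = Grid(
        tuple(s - 1 for s in grid_half.shape),
        grid_half.spacing,
        tuple(o + delta * sp for o, sp in zip(grid_half.origin, grid_half.spacing)),
    )
    identity = AffineTransform(center_mm=center)
    fixed_probe_fine = resample_volume(
        fixed_s, grid, identity, out_grid=probe_fine, cval=0.0
    )
    fixed_probe_half = resample_volume(
        fixed_s, grid, identity, out_grid=probe_half, cval=0.0
    )
    f1, m1 = _downsample(fixed), _downsample(moving)
    # stage 1: bulk misalignment on the cheap downsampled pair; stage 2:
    # full mobility on the half-density probe of the smoothed fine images
    # (correct landscape, quarter cost); stage 3: small-simplex polish on
    # the full-density probe
    # the probe stage runs twice: a fresh full-size simplex recovers from
    # premature Nelder-Mead collapse in the narrow, correlated valley
    levels = [
        (f1, m1, grid_half, grid_half, 1.0, 2 * maxiter),
        (fixed_probe_half, moving_s, grid, probe_half, 1.0, 2 * maxiter),
        (fixed_probe_half, moving_s, grid, probe_half, 1.0, 2 * maxiter),
        (fixed_probe_fine, moving_s, grid, probe_fine, 0.06, maxiter // 3),
    ]

    def neg_nmi(p: np.ndarray, fvol, mvol, g_in, g_out) -> float:
        if np.any(p[6:9] <= 0.5) or np.any(p[6:9] >= 2.0):
            return 0.0
        t = AffineTransform.from_params(p, center_mm=center)
        res = resample_volume(mvol, g_in, t, out_grid=g_out)
        try:
            return -normalized_mutual_information(fvol, res, bins=bins)
        except ValueError:
            return 0.0

    base_steps = np.array([2.0, 2.0, 2.0, 2.0, 2.0, 2.0, 0.04, 0.04, 0.04])
    base_steps[:3] *= min(grid.spacing)
    p0 = init.params
    base_score = neg_nmi(p0, *levels[-1][:4])

    best_p, best_score = p0.copy(), base_score
    improved = False
    for start in range(max(1, n_starts)):
        p = p0.copy() if start == 0 else p0 + rng.normal(0, 0.5, 9) * base_steps
        p[6:9] = np.clip(p[6:9], 0.8, 1.25)
        for fvol, mvol, g_in, g_out, step_frac, iters in levels:
            res = optimize.minimize(
                neg_nmi,
                p,
                args=(fvol, mvol, g_in, g_out),
                method="Nelder-Mead",
                options={
                    "maxiter": iters,
                    "xatol": 1e-4,
                    "fatol": 1e-8,
                    "initial_simplex": _simplex(p, base_steps * step_frac),
                },
            )
            p = res.x
        score = neg_nmi(p, *levels[-1][:4])
        if score < best_score - 1e-12:
            best_p, best_score = p, score
            improved = True
            break
    if not improved:
        warnings.warn("registration did not improve on the initial transform")
        return init
    return AffineTransform.from_params(best_p, center_mm=center)


def _simplex(p: np.ndarray, steps: np.ndarray) -> np.ndarray:
    sim = np.tile(p, (len(p) + 1, 1))
    for i in range(len(p)):
        sim[i + 1, i] += steps[i]
    return sim


def transform_mesh(mesh: SurfaceMesh, t: AffineTransform) -> SurfaceMesh:
    """Map mesh vertices through ``t``; radii scale by the mean scale factor."""
    verts = t.apply_points(mesh.vertices) if mesh.n_vertices else mesh.vertices.copy()
    rad = mesh.vertex_radius
    if rad is not None:
        rad = rad * float(np.mean(t.scale))
    return SurfaceMesh(verts, mesh.faces.copy(), rad)
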