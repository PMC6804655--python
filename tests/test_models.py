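"""Model generation: masking, isosurfaces, cleanup, centrelines, pruning."""

import warnings

import numpy as np
import pytest

import seegplan as sp
from seegplan.grids import Grid
from seegplan.mesh import MeshDistanceQuery, SurfaceMesh, concatenate_meshes
from seegplan.models import (
    apply_intracranial_mask,
    auto_threshold,
    extract_centerline_radii,
    extract_sulcal_model,
    extract_vessel_surface,
    prune_by_diameter,
    remove_small_components,
    segment_vessels,
)
from seegplan.phantom import ModalityProfile, render_modality, tree_to_mesh

from conftest import make_ball_volume, make_tube_volume


class TestApplyIntracranialMask:
    def test_all_ones_is_identity(self, small_grid):
        rng = np.random.default_rng(0)
        img = rng.normal(size=small_grid.shape)
        out = apply_intracranial_mask(img, np.ones(small_grid.shape, bool))
        np.testing.assert_array_equal(out, img)

    def test_all_zeros_clears_volume(self, small_grid):
        img = np.ones(small_grid.shape)
        out = apply_intracranial_mask(img, np.zeros(small_grid.shape, bool))
        assert np.all(out == 0)

    def test_half_space_mask_counts(self, small_grid):
        img = np.ones(small_grid.shape)
        mask = np.zeros(small_grid.shape, bool)
        mask[:24] = True
        out = apply_intracranial_mask(img, mask)
        assert (out != 0).sum() == mask.sum()

    def test_idempotent(self, small_grid):
        rng = np.random.default_rng(1)
        img = rng.normal(size=small_grid.shape)
        mask = rng.random(small_grid.shape) > 0.5
        once = apply_intracranial_mask(img, mask)
        twice = apply_intracranial_mask(once, mask)
        np.testing.assert_array_equal(once, twice)

    def test_grid_mismatch_raises(self):
        with pytest.raises(ValueError, match="grid mismatch"):
            apply_intracranial_mask(np.zeros((4, 4, 4)), np.zeros((5, 5, 5), bool))


class TestExtractVesselSurface:
    def test_ball_surface_radius(self, small_grid):
        vol = make_ball_volume(small_grid, (0, 0, 0), 10.0)
        mesh = extract_vessel_surface(vol, small_grid, 0.5)
        r = np.linalg.norm(mesh.vertices, axis=1)
        assert np.all(np.abs(r - 10.0) <= 1.0)

    def test_threshold_above_maximum_raises(self, small_grid):
        vol = make_ball_volume(small_grid, (0, 0, 0), 10.0)
        with pytest.raises(ValueError, match="outside intensity range"):
            extract_vessel_surface(vol, small_grid, 2.0)

    def test_cylinder_surface_area(self, small_grid):
        # tube crossing the whole volume: open isosurface, area ~ 2*pi*r*L
        vol = make_tube_volume(small_grid, (-30, 0, 0), (30, 0, 0), 3.0, smooth=1.0)
        mesh = extract_vessel_surface(vol, small_grid, 0.5)
        L = small_grid.shape[0] * small_grid.spacing[0]
        expect = 2 * np.pi * 3.0 * L
        assert abs(mesh.area() - expect) / expect < 0.15


class TestRemoveSmallComponents:
    def _specked_mesh(self):
        import trimesh

        tube = make_tube_volume(Grid((48,) * 3, (1.0,) * 3, (-24.0,) * 3),
                                (-20, 0, 0), (20, 0, 0), 3.0, smooth=1.0)
        grid = Grid((48,) * 3, (1.0,) * 3, (-24.0,) * 3)
        main = extract_vessel_surface(tube, grid, 0.5)
        specks = []
        for k in range(5):
            tm = trimesh.creation.icosphere(subdivisions=0, radius=0.5)  # 12 verts
            s = SurfaceMesh(np.asarray(tm.vertices) + [0, 15, 5 * k - 10],
                            np.asarray(tm.faces))
            specks.append(s)
        return main, concatenate_meshes([main] + specks)

    def test_keeps_only_large_component(self):
        main, noisy = self._specked_mesh()
        cleaned = remove_small_components(noisy, min_vertices=50)
        assert cleaned.n_vertices == main.n_vertices
        assert len(np.unique(cleaned.vertex_components())) == 1

    def test_zero_threshold_is_identity(self):
        _, noisy = self._specked_mesh()
        out = remove_small_components(noisy, 0)
        assert out.n_vertices == noisy.n_vertices

    def test_all_below_threshold_empties_mesh(self):
        _, noisy = self._specked_mesh()
        out = remove_small_components(noisy, noisy.n_vertices + 1)
        assert out.is_empty


class TestExtractSulcalModel:
    def test_zero_erosion_keeps_full_gm_surface(self, small_grid):
        gm = make_ball_volume(small_grid, (0, 0, 0), 10.0) > 0.5
        icv = make_ball_volume(small_grid, (0, 0, 0), 20.0) > 0.5
        mesh = extract_sulcal_model(gm, icv, small_grid, erosion_mm=0.0)
        r = np.linalg.norm(mesh.vertices, axis=1)
        assert np.all(np.abs(r - 10.0) <= 1.0)

    def test_superficial_ribbon_vanishes_under_erosion(self, small_grid):
        icv = make_ball_volume(small_grid, (0, 0, 0), 20.0) > 0.5
        shell = icv & (make_ball_volume(small_grid, (0, 0, 0), 17.0) <= 0.5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mesh = extract_sulcal_model(shell, icv, small_grid, erosion_mm=5.0)
        assert mesh.is_empty

    def test_deep_fold_survives_erosion(self, small_grid):
        # voxel-wise oracle: surviving voxels = gm AND eroded icv
        from scipy import ndimage
        from skimage.morphology import ball

        icv = make_ball_volume(small_grid, (0, 0, 0), 20.0) > 0.5
        pts = small_grid.voxel_centers()
        fold = (
            (np.abs(pts[..., 1]) <= 1.5)
            & (pts[..., 0] >= 5.0)
            & (pts[..., 0] <= 20.0)
            & (np.abs(pts[..., 2]) <= 8.0)
        ) & icv
        mesh = extract_sulcal_model(fold, icv, small_grid, erosion_mm=5.0)
        eroded = ndimage.binary_erosion(icv, structure=ball(5))
        oracle = fold & eroded
        assert oracle.any() and not mesh.is_empty
        # every mesh vertex lies near the oracle voxel set
        inside = small_grid.contains_points(
            ndimage.binary_dilation(oracle), mesh.vertices
        )
        assert inside.mean() > 0.95


def analytic_tube_mesh(radius, start=(-18.0, 0, 0), end=(18.0, 0, 0)):
    tree = sp.VascularTree(
        starts=np.array([start], float), ends=np.array([end], float),
        radii=np.array([radius]), parents=np.array([-1]), roots=np.zeros((1, 3)),
    )
    return tree_to_mesh(tree)


class TestCenterlineRadii:
    def test_cylinder_radius_recovery(self, small_grid):
        out = extract_centerline_radii(analytic_tube_mesh(2.0), small_grid)
        assert 1.5 <= np.median(out.vertex_radius) <= 2.5

    def test_sphere_degenerates_to_centroid(self, small_grid):
        import trimesh

        tm = trimesh.creation.icosphere(subdivisions=3, radius=8.0)
        mesh = sp.SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
        out = extract_centerline_radii(mesh, small_grid)
        assert np.all(np.abs(out.vertex_radius - 8.0) <= 1.0)
        assert abs(np.median(out.vertex_radius) - 8.0) <= 0.5

    def test_branch_radius_ordering(self, small_grid):
        vol = np.maximum(
            make_tube_volume(small_grid, (-18, -8, 0), (18, -8, 0), 1.0),
            make_tube_volume(small_grid, (-18, 8, 0), (18, 8, 0), 3.0),
        )
        mesh = extract_vessel_surface(vol, small_grid, 0.5)
        out = extract_centerline_radii(mesh, small_grid)
        thin = out.vertices[:, 1] < 0
        assert np.median(out.vertex_radius[thin]) < np.median(
            out.vertex_radius[~thin]
        )

    def test_empty_mesh_raises(self, small_grid):
        with pytest.raises(ValueError):
            extract_centerline_radii(SurfaceMesh.empty(), small_grid)


class TestPruneByDiameter:
    def _labelled_tree_mesh(self):
        tree = sp.VascularTree(
            starts=np.array([[-15, -10, 0], [-15, 0, 0], [-15, 10, 0]], float),
            ends=np.array([[15, -10, 0], [15, 0, 0], [15, 10, 0]], float),
            radii=np.array([0.5, 1.5, 2.5]),  # diameters 1, 3, 5 mm
            parents=np.array([-1, -1, -1]),
            roots=np.zeros((3, 3)),
        )
        return tree_to_mesh(tree)

    def test_zero_threshold_is_identity(self):
        mesh = self._labelled_tree_mesh()
        out = prune_by_diameter(mesh, 0.0)
        assert out.n_vertices == mesh.n_vertices

    def test_uniformly_thin_mesh_empties(self):
        tree = sp.VascularTree(
            starts=np.array([[-10, 0, 0]], float), ends=np.array([[10, 0, 0]], float),
            radii=np.array([0.5]), parents=np.array([-1]), roots=np.zeros((1, 3)),
        )
        out = prune_by_diameter(tree_to_mesh(tree), 2.0)
        assert out.is_empty

    @pytest.mark.parametrize(
        "threshold,expected_diams",
        [(1.0, {1.0, 3.0, 5.0}), (2.0, {3.0, 5.0}), (3.0, {3.0, 5.0}), (4.0, {5.0})],
    )
    def test_branch_survival_sets(self, threshold, expected_diams):
        mesh = self._labelled_tree_mesh()
        out = prune_by_diameter(mesh, threshold)
        survived = set(np.round(2 * np.unique(out.vertex_radius), 6))
        assert survived == expected_diams

    def test_pruning_nesting(self):
        mesh = self._labelled_tree_mesh()
        prev = None
        for t in (1.0, 2.0, 3.0, 4.0):
            cur = {tuple(v) for v in prune_by_diameter(mesh, t).vertices}
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_missing_radii_raises(self):
        mesh = self._labelled_tree_mesh()
        mesh.vertex_radius = None
        with pytest.raises(ValueError, match="vertex_radius"):
            prune_by_diameter(mesh, 1.0)


class TestEndToEndSegmentation:
    def test_noiseless_recall_of_thick_segments(self, default_phantom):
        """Every truth segment at least two voxels across leaves surface
        vertices within one voxel of its analytic tube surface."""
        ph = default_phantom
        prof = ModalityProfile("clean", 0.0, blur_sigma=0.5, noise_sd=0.0)
        img = render_modality(ph.tree, prof, ph.grid, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mesh = segment_vessels(
                img, ph.grid, ph.intracranial_mask, compute_radii=False
            )
        assert not mesh.is_empty
        from scipy.spatial import cKDTree

        vtree = cKDTree(mesh.vertices)
        vox = min(ph.grid.spacing)
        misses = 0
        checked = 0
        for i in range(ph.tree.n_segments):
            if ph.tree.diameters[i] < 2 * vox:
                continue
            mid = 0.5 * (ph.tree.starts[i] + ph.tree.ends[i])
            axis = ph.tree.ends[i] - ph.tree.starts[i]
            perp = np.cross(axis, [0.0, 0.0, 1.0])
            if np.linalg.norm(perp) < 1e-6:
                perp = np.cross(axis, [0.0, 1.0, 0.0])
            perp /= np.linalg.norm(perp)
            # probe a surface point not swallowed by an overlapping tube
            surf_pt = None
            for ang in np.linspace(0, 2 * np.pi, 8, endpoint=False):
                rot = perp * np.cos(ang) + np.cross(
                    axis / np.linalg.norm(axis), perp
                ) * np.sin(ang)
                p = mid + rot * ph.tree.radii[i]
                others = [
                    j for j in range(ph.tree.n_segments) if j != i
                ]
                from seegplan.phantom import _point_segment_distance

                clear = all(
                    _point_segment_distance(
                        p[None, :], ph.tree.starts[j], ph.tree.ends[j]
                    )[0]
                    > ph.tree.radii[j] + 0.1
                    for j in others
                )
                if clear:
                    surf_pt = p
                    break
            if surf_pt is None:
                continue  # fully overlapped by neighbouring tubes
            checked += 1
            d, _ = vtree.query(surf_pt)
            if d > vox:
                misses += 1
        assert checked > 0
        assert misses == 0, f"{misses}/{checked} thick segments missed"


def test_auto_threshold_lies_inside_positive_range(small_grid):
    vol = make_tube_volume(small_grid, (-18, 0, 0), (18, 0, 0), 2.0, smooth=1.0)
    from seegplan.vesselness import sato_vesselness

    v = sato_vesselness(vol, small_grid)
    t = auto_threshold(v)
    assert 0 < t < v.max()
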