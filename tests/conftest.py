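"""Shared fixtures: phantoms and the two cohort studies.

The cohort fixtures are session-scoped because they are the expensive part
of the suite (10 phantoms, three vessel models each, full planning and
cross-evaluation); several acceptance-level tests read different aspects
of the same run.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import seegplan as sp
from seegplan.config import StudyConfig
from seegplan.evaluation import run_study
from seegplan.grids import Grid


@pytest.fixture(scope="session")
def default_phantom() -> sp.Phantom:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sp.make_phantom(7)


@pytest.fixture(scope="session")
def analytic_gold(default_phantom) -> sp.SurfaceMesh:
    """Ground-truth tube mesh of the full tree, true per-vertex radii."""
    return sp.tree_to_mesh(default_phantom.tree)


@pytest.fixture(scope="session")
def analytic_study():
    """Noiseless 10-phantom cohort: models are truth tube meshes."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_study(
            1, StudyConfig(model_source="analytic"), keep_artifacts=True
        )


@pytest.fixture(scope="session")
def imaging_study():
    """Full-chain 10-phantom cohort: models segmented from noisy renders."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_study(
            1, StudyConfig(model_source="imaging"), keep_artifacts=True
        )


@pytest.fixture
def small_grid() -> Grid:
    return Grid((48, 48, 48), (1.0, 1.0, 1.0), (-24.0, -24.0, -24.0))


def make_tube_volume(grid: Grid, start, end, radius, smooth=0.0) -> np.ndarray:
    """Binary (optionally smoothed) tube occupancy used across tests."""
    from scipy import ndimage

    from seegplan.phantom import _point_segment_distance

    pts = grid.voxel_centers().reshape(-1, 3)
    d = _point_segment_distance(pts, np.asarray(start, float), np.asarray(end, float))
    vol = (d <= radius).reshape(grid.shape).astype(float)
    if smooth:
        vol = ndimage.gaussian_filter(vol, smooth)
    return vol


def make_ball_volume(grid: Grid, center, radius, smooth=0.0) -> np.ndarray:
    from scipy import ndimage

    pts = grid.voxel_centers()
    vol = (np.linalg.norm(pts - np.asarray(center, float), axis=-1) <= radius).astype(float)
    if smooth:
        vol = ndimage.gaussian_filter(vol, smooth)
    return vol
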