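"""Multiscale Hessian line filter for bright tubular structures.

Implements the Sato line measure: at each scale the image is convolved with
Gaussian second derivatives (sigma in mm), the Hessian is
scale-normalised by sigma^2, and the response is built from the ordered
eigenvalues l1 >= l2 >= l3.  A bright tube has l2, l3 strongly negative
and l1 near zero; the response is zero wherever l2 or l3 is
non-negative.  The multiscale output is the maximum over scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import Grid


@dataclass(frozen=True)
class VesselnessParams:
    """Scales (mm) and shape weights of the line filter.

    alpha controls tolerance of the asymmetry between the tube cross-section
    eigenvalues and the axial one; gamma12/gamma23 are the sharpness
    exponents of the two eigenvalue ratios.
    """

    scales: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0)
    alpha: float = 0.25
    gamma12: float = 1.0
    gamma23: float = 1.0

    def __post_init__(self) -> None:
        if len(self.scales) == 0 or any(s <= 0 for s in self.scales):
            raise ValueError("scales must be a nonempty list of positive mm values")


def _hessian_eigenvalues(image: np.ndarray, sigma_vox: np.ndarray) -> np.ndarray:
    """Sorted (descending) eigenvalues of the Gaussian Hessian, (*, 3)."""
    h = np.empty(image.shape + (3, 3), dtype=np.float32)
    orders = {(0, 0): (2, 0, 0), (1, 1): (0, 2, 0), (2, 2): (0, 0, 2),
              (0, 1): (1, 1, 0), (0, 2): (1, 0, 1), (1, 2): (0, 1, 1)}
    for (i, j), order in orders.items():
        d = ndimage.gaussian_filter(image, sigma_vox, order=order).astype(np.float32)
        h[..., i, j] = d
        if i != j:
            h[..., j, i] = d
    ev = np.linalg.eigvalsh(h.reshape(-1, 3, 3))  # ascending
    return ev[:, ::-1].reshape(image.shape + (3,))  # descending l1 >= l2 >= l3


def sato_response_single_scale(
    image: np.ndarray, grid: Grid, sigma_mm: float, params: VesselnessParams
) -> np.ndarray:
    """sigma^2-normalised line response at one scale."""
    sigma_vox = sigma_mm / grid.spacing_arr
    ev = _hessian_eigenvalues(np.asarray(image, dtype=np.float32), sigma_vox)
    l1 = ev[..., 0].astype(np.float64) * sigma_mm**2
    l2 = ev[..., 1].astype(np.float64) * sigma_mm**2
    l3 = ev[..., 2].astype(np.float64) * sigma_mm**2

    out = np.zeros_like(l1)
    tube = (l2 < 0) & (l3 < 0)
    if not tube.any():
        return out
    a2 = np.abs(l2)
    base = np.zeros_like(l1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio23 = np.where(tube, l2 / l3, 0.0)
    base[tube] = np.abs(l3[tube]) * ratio23[tube] ** params.gamma23

    neg = tube & (l1 <= 0)
    out[neg] = base[neg] * (1.0 + l1[neg] / a2[neg]) ** params.gamma12
    if params.alpha > 0:
        pos = tube & (l1 > 0) & (l1 < a2 / params.alpha)
        out[pos] = base[pos] * (1.0 - params.alpha * l1[pos] / a2[pos]) ** params.gamma12
    np.maximum(out, 0.0, out=out)
    return out


def sato_vesselness(
    image: np.ndarray, grid: Grid, params: VesselnessParams | None = None
) -> np.ndarray:
    """Maximum line response over the configured scales (bright vessels)."""
    image = np.asarray(image)
    if image.ndim != 3:
        raise ValueError("vesselness filter expects a 3-D volume")
    params = params or VesselnessParams()
    out = None
    for s in params.scales:
        r = sato_response_single_scale(image, grid, s, params)
        out = r if out is None else np.maximum(out, r)
    return out
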