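"""Autodetection of candidate feature points.

Points with distinct tissue features are selected from the gradient field:
a voxel is a candidate when its intensity falls inside a tissue window (CT
numbers: bone above 100, soft tissue such as pancreas between 0 and 100) and
its local gradient energy — the sum of squared gradient magnitudes over the
3×3×3 neighbourhood — is high.  Candidates are reduced to strict local maxima
of that saliency within a physical radius, thresholded, sorted and capped.

The matcher, not the detector, carries the discriminative burden: the
detector only has to propose well-textured, reproducible locations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import VolumeImage

__all__ = [
    "FeaturePoint",
    "DetectionConfig",
    "BONE_WINDOW",
    "PANCREAS_WINDOW",
    "compute_gradient",
    "detect_feature_points",
]

logger = logging.getLogger(__name__)

#: CT-number tissue windows: bone above 100 HU, pancreas between 0 and 100 HU.
BONE_WINDOW = (100.0, np.inf)
PANCREAS_WINDOW = (0.0, 100.0)


@dataclass(frozen=True)
class FeaturePoint:
    """A detected voxel with its physical position and saliency score."""

    index: tuple[int, int, int]
    position: tuple[float, float, float]  # mm
    saliency: float


@dataclass
class DetectionConfig:
    """Detector parameters.

    Parameters
    ----------
    intensity_window
        ``(low, high)`` in image units; only voxels inside the window are
        candidates (tissue selection).
    min_saliency
        Absolute saliency threshold.  ``None`` selects the
        ``saliency_quantile`` quantile of in-window saliency.
    saliency_quantile
        Quantile used when ``min_saliency`` is ``None``; default 0.9.
    nms_radius
        Physical radius (mm) of the local-maximum test; 0 disables NMS.
    max_points
        Cap on the number of returned points (strongest kept).
    border_margin
        Voxels excluded at every image face; must be ≥ 4 so the 8×8×8
        descriptor window fits around every returned point.
    """

    intensity_window: tuple[float, float] = (0.0, 3000.0)
    min_saliency: float | None = None
    saliency_quantile: float = 0.9
    nms_radius: float = 3.0
    max_points: int = 10_000
    border_margin: int = 4

    def __post_init__(self) -> None:
        low, high = self.intensity_window
        if low > high:
            raise ValueError(f"intensity window low {low} > high {high}")
        if self.nms_radius < 0:
            raise ValueError("nms_radius must be >= 0")
        if self.max_points < 1:
            raise ValueError("max_points must be >= 1")
        if self.border_margin < 4:
            raise ValueError(
                "border_margin must be >= 4 (half the 8x8x8 descriptor window)"
            )
        if not 0.0 <= self.saliency_quantile <= 1.0:
            raise ValueError("saliency_quantile must be in [0, 1]")


def compute_gradient(image: VolumeImage) -> np.ndarray:
    """Per-voxel central-difference gradient, shape ``dims + (3,)``.

    The gradient along each axis at voxel (i, j, k) is half the difference of
    the two axis neighbours, e.g. (1/2)(I[i+1,j,k] − I[i−1,j,k]) along x, in
    image units per voxel step.  Boundary voxels use replicated-edge
    neighbours.  For single-slice (2-D) images the z component is zero.
    """
    data = image.data
    grad = np.zeros(data.shape + (3,), dtype=np.float64)
    for ax in range(3):
        n = data.shape[ax]
        if n == 1:
            if ax == 2:
                continue  # 2-D image: z gradient identically zero
            raise ValueError(f"axis {ax} is degenerate (size 1)")
        if n < 3:
            raise ValueError(
                f"axis {ax} has {n} voxels; central differences need >= 3"
            )
        pad = [(0, 0)] * 3
        pad[ax] = (1, 1)
        padded = np.pad(data, pad, mode="edge")
        hi = [slice(None)] * 3
        lo = [slice(None)] * 3
        hi[ax] = slice(2, None)
        lo[ax] = slice(0, -2)
        grad[..., ax] = 0.5 * (padded[tuple(hi)] - padded[tuple(lo)])
    return grad


def _saliency(grad: np.ndarray, is_2d: bool) -> np.ndarray:
    """Sum of squared gradient magnitudes over each 3×3×3 neighbourhood."""
    energy = np.sum(grad * grad, axis=-1)
    size = (3, 3, 1) if is_2d else (3, 3, 3)
    # uniform_filter averages; multiply back to a sum over the window.
    return ndimage.uniform_filter(energy, size=size, mode="nearest") * np.prod(size)


def _nms_offsets(spacing: tuple[float, float, float], radius: float,
                 is_2d: bool) -> np.ndarray:
    """Voxel offsets within the physical NMS radius (centre excluded)."""
    r = [int(np.floor(radius / s)) for s in spacing]
    if is_2d:
        r[2] = 0
    ox, oy, oz = np.meshgrid(
        *(np.arange(-ri, ri + 1) for ri in r), indexing="ij"
    )
    d2 = (ox * spacing[0]) ** 2 + (oy * spacing[1]) ** 2 + (oz * spacing[2]) ** 2
    keep = (d2 <= radius * radius + 1e-12) & (d2 > 0)
    return np.stack([ox[keep], oy[keep], oz[keep]], axis=1)


def detect_feature_points(
    image: VolumeImage, config: DetectionConfig | None = None
) -> list[FeaturePoint]:
    """Detect feature points in a volume.

    Every returned point has intensity inside the configured window, saliency
    ≥ the (possibly quantile-derived) threshold, survives greedy non-maximum
    suppression within ``nms_radius`` (candidates are visited strongest
    first, equal-saliency ties in the smaller lexicographic index's favour,
    and each accepted point suppresses all weaker candidates within the
    radius — so returned points are pairwise more than ``nms_radius`` apart),
    and lies at least ``border_margin`` voxels from every image face.
    Suppression runs before thresholding, so raising ``min_saliency`` only
    ever removes points.  Points are sorted by descending saliency (ties by
    lexicographic index) and truncated at ``max_points``.  The procedure is
    deterministic.
    """
    if config is None:
        config = DetectionConfig()
    data = image.data
    grad = compute_gradient(image)
    sal = _saliency(grad, image.is_2d)

    low, high = config.intensity_window
    mask = (data >= low) & (data <= high)
    m = config.border_margin
    border = np.zeros_like(mask)
    if image.is_2d:
        if data.shape[0] > 2 * m and data.shape[1] > 2 * m:
            border[m : data.shape[0] - m, m : data.shape[1] - m, :] = True
    else:
        if all(s > 2 * m for s in data.shape):
            border[m : data.shape[0] - m, m : data.shape[1] - m,
                   m : data.shape[2] - m] = True
    mask &= border
    # zero gradient energy is never a feature (constant regions)
    mask &= sal > 0

    if not np.any(mask):
        logger.warning("detect_feature_points: no candidate voxels")
        return []

    idx = np.argwhere(mask)
    sal_v = sal[mask]

    # greedy NMS over all candidates (threshold-independent), strongest first
    if config.nms_radius > 0 and len(idx) > 1:
        offsets = _nms_offsets(image.spacing, config.nms_radius, image.is_2d)
        order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], -sal_v))
        suppressed = np.zeros(image.dims, dtype=bool)
        dims = np.asarray(image.dims)
        kept = []
        for row in order:
            i, j, k = idx[row]
            if suppressed[i, j, k]:
                continue
            kept.append(row)
            nb = offsets + idx[row]
            ok = np.all((nb >= 0) & (nb < dims), axis=1)
            nb = nb[ok]
            suppressed[nb[:, 0], nb[:, 1], nb[:, 2]] = True
        kept = np.asarray(kept, dtype=int)
        idx = idx[kept]
        sal_v = sal_v[kept]

    threshold = config.min_saliency
    if threshold is None:
        in_window = sal[mask]
        threshold = float(np.quantile(in_window, config.saliency_quantile))
    keep = sal_v >= threshold
    idx = idx[keep]
    sal_v = sal_v[keep]

    if len(idx) == 0:
        logger.warning("detect_feature_points: no points above saliency threshold")
        return []

    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], -sal_v))
    idx = idx[order][: config.max_points]
    sal_v = sal_v[order][: config.max_points]

    positions = image.index_to_physical(idx)
    return [
        FeaturePoint(tuple(int(v) for v in ijk), tuple(map(float, p)), float(s))
        for ijk, p, s in zip(idx, positions, sal_v)
    ]
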