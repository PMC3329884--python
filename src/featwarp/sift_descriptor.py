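"""Orientation-histogram (SIFT-style) descriptors for feature points.

A feature point's signature is the orientation distribution of intensity
gradient vectors in its 8×8×8-voxel neighbourhood, split into eight octant
quadrants of 4×4×4 voxels.  For each quadrant and each of the three
coordinate planes (xy, yz, zx), the in-plane projection of every voxel
gradient is binned by its in-plane angle into eight 45° bins covering
[0°, 360°), accumulating the in-plane gradient magnitude.  This yields
8 quadrants × 3 planes × 8 bins = 192 components in 3-D.

Single-slice (2-D) images use the planar analogue: an 8×8 window, four 4×4
quadrants and the xy plane only — 32 components — and 2-D descriptors are
never comparable with 3-D ones.

Conventions (fixed for reproducibility):

* the window spans offsets [−4, +3] about the centre voxel along each axis;
* quadrant index is the bit code ``(ox≥0)<<2 | (oy≥0)<<1 | (oz≥0)``
  (``(ox≥0)<<1 | (oy≥0)`` in 2-D);
* in-plane angles are ``atan2`` of (gy, gx) for xy, (gz, gy) for yz and
  (gz, gx) for zx, mapped to [0°, 360°); bin b covers [45°·b, 45°·(b+1)),
  so an angle exactly on an edge goes to the higher bin;
* gradients are in image units per voxel step (no spacing scaling), so
  anisotropic spacing makes the descriptor anisotropic as well;
* components are ordered (quadrant, plane, bin), quadrant-major.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import VolumeImage
from .feature_detection import FeaturePoint, compute_gradient

__all__ = [
    "SiftDescriptor",
    "compute_descriptor",
    "compute_descriptors",
    "descriptor_distance",
]

#: (first-axis, second-axis) gradient component pairs per plane.
_PLANES_3D = ((0, 1), (1, 2), (0, 2))  # xy, yz, zx
_HALF = 4  # window spans [-4, +3] -> 8 voxels per axis


@dataclass
class SiftDescriptor:
    """A 192-component (3-D) or 32-component (2-D) orientation histogram."""

    values: np.ndarray
    point: FeaturePoint
    mode: str  # "3d" or "2d"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        expected = 192 if self.mode == "3d" else 32
        if self.mode not in ("2d", "3d"):
            raise ValueError(f"mode must be '2d' or '3d', got {self.mode!r}")
        if self.values.shape != (expected,):
            raise ValueError(
                f"{self.mode} descriptor must have {expected} components, "
                f"got shape {self.values.shape}"
            )
        if np.any(self.values < 0):
            raise ValueError("descriptor entries must be non-negative")


def _window_offsets(is_2d: bool) -> tuple[np.ndarray, np.ndarray]:
    """Window offset table and per-offset quadrant index."""
    offs = np.arange(-_HALF, _HALF)
    if is_2d:
        ox, oy = np.meshgrid(offs, offs, indexing="ij")
        table = np.stack(
            [ox.ravel(), oy.ravel(), np.zeros(ox.size, dtype=int)], axis=1
        )
        quad = ((table[:, 0] >= 0).astype(int) << 1) | (table[:, 1] >= 0)
    else:
        ox, oy, oz = np.meshgrid(offs, offs, offs, indexing="ij")
        table = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)
        quad = (
            ((table[:, 0] >= 0).astype(int) << 2)
            | ((table[:, 1] >= 0).astype(int) << 1)
            | (table[:, 2] >= 0)
        )
    return table, quad


def _check_window(image: VolumeImage, points: list[FeaturePoint]) -> None:
    dims = image.dims
    axes = (0, 1) if image.is_2d else (0, 1, 2)
    for p in points:
        for ax in axes:
            if p.index[ax] - _HALF < 0 or p.index[ax] + _HALF - 1 >= dims[ax]:
                raise ValueError(
                    f"descriptor window out of bounds for point {p.index} "
                    f"in image of dims {dims}"
                )


def compute_descriptors(
    image: VolumeImage,
    points: list[FeaturePoint],
    *,
    weight: str = "magnitude",
    normalize: bool = False,
    batch: int = 2048,
) -> list[SiftDescriptor]:
    """Build descriptors for many points sharing one gradient computation.

    ``weight`` is ``"magnitude"`` (classical: accumulate in-plane gradient
    magnitude; zero-magnitude projections contribute nothing) or ``"count"``
    (accumulate 1 per voxel with a nonzero in-plane projection).
    ``normalize`` rescales each descriptor to unit L2 norm (off by default:
    raw histograms are what the matching distance compares).
    """
    if weight not in ("magnitude", "count"):
        raise ValueError(f"unknown weight scheme {weight!r}")
    _check_window(image, points)
    is_2d = image.is_2d
    mode = "2d" if is_2d else "3d"
    nbins = 32 if is_2d else 192
    grad = compute_gradient(image)
    table, quad = _window_offsets(is_2d)
    planes = (_PLANES_3D[0],) if is_2d else _PLANES_3D

    out: list[SiftDescriptor] = []
    for start in range(0, len(points), batch):
        chunk = points[start : start + batch]
        nb = len(chunk)
        idx = np.asarray([p.index for p in chunk], dtype=np.int64)
        coords = idx[:, None, :] + table[None, :, :]  # (nb, win, 3)
        g = grad[coords[..., 0], coords[..., 1], coords[..., 2]]  # (nb, win, 3)
        values = np.zeros(nb * nbins)
        for pi, (a, b) in enumerate(planes):
            ga, gb = g[..., a], g[..., b]
            mag = np.hypot(ga, gb)
            ang = np.degrees(np.arctan2(gb, ga)) % 360.0
            bins = (ang // 45.0).astype(np.int64) % 8
            flat = quad[None, :] * (8 * len(planes)) + pi * 8 + bins
            flat = flat + np.arange(nb)[:, None] * nbins
            w = mag if weight == "magnitude" else (mag > 0).astype(np.float64)
            values += np.bincount(flat.ravel(), weights=w.ravel(),
                                  minlength=nb * nbins)
        values = values.reshape(nb, nbins)
        if normalize:
            norms = np.linalg.norm(values, axis=1, keepdims=True)
            np.divide(values, norms, out=values, where=norms > 0)
        out.extend(
            SiftDescriptor(values[i].copy(), chunk[i], mode) for i in range(nb)
        )
    return out


def compute_descriptor(
    image: VolumeImage,
    point: FeaturePoint,
    *,
    weight: str = "magnitude",
    normalize: bool = False,
) -> SiftDescriptor:
    """Descriptor for a single feature point (window must fit in the image)."""
    return compute_descriptors(
        image, [point], weight=weight, normalize=normalize
    )[0]


def descriptor_distance(a: SiftDescriptor, b: SiftDescriptor) -> float:
    """Least-squares descriptor difference S = Σ_α |a_α − b_α|².

    Symmetric, non-negative, and zero iff the descriptors are componentwise
    equal.  2-D and 3-D descriptors are never comparable.
    """
    if a.mode != b.mode:
        raise ValueError(f"descriptor mode mismatch: {a.mode} vs {b.mode}")
    d = a.values - b.values
    return float(np.dot(d, d))
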