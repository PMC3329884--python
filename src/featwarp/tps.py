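"""Thin-plate-spline fitting, evaluation, dense fields and image warping.

Given n matched control points, the TPS interpolant for each output
coordinate is

    f(x) = a1 + a·x + Σ_i w_i · U(|p_i − x|),        U(r) = r² log r²,

with the weights W and affine coefficients (a1, a_u, a_v, a_w) obtained from
the linear system L · (W | a)ᵀ = Y, where L = [[K, P], [Pᵀ, O]], K holds
U(r_ij) with a zero diagonal, P = [1 | p_i] and Y stacks the destination
coordinates over zeros.  The Pᵀ block enforces the side conditions
Σ w_i = 0 and Σ w_i p_i = 0, so the interpolant is exactly affine when the
correspondence is affine, and exact at every control point otherwise.

``U(r) = r² log r²`` is the classical 2-D TPS kernel; it is applied in 3-D
as well, exactly as the registration method defines it, with the true 3-D
biharmonic kernel ``U(r) = r`` available as an option.

Direction convention: the model is fitted with source = target-image
landmarks and destination = template-image landmarks, so the resulting dense
displacement field supports backward warping (no holes in the resampled
image).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg, ndimage
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .core_io import (DisplacementField, LandmarkSet, VolumeImage,
                      _snap_to_grid)

__all__ = ["TPSModel", "kernel_U", "fit_tps", "evaluate_tps",
           "tps_to_field", "warp_image"]

logger = logging.getLogger(__name__)

_EVAL_CHUNK = 65_536
_DUPLICATE_TOL = 1e-6  # mm


def kernel_U(r, kind: str = "r2logr2"):
    """TPS radial basis U(r) = r² log r² (limit 0 at r = 0), or U(r) = r.

    Accepts scalars or arrays; negative distances raise.
    """
    arr = np.asarray(r, dtype=np.float64)
    if np.any(arr < 0):
        raise ValueError("distances must be non-negative")
    if kind == "r2logr2":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(arr > 0, arr * arr * np.log(arr * arr), 0.0)
    elif kind == "r":
        out = arr.copy()
    else:
        raise ValueError(f"unknown kernel kind {kind!r}")
    if np.isscalar(r):
        return float(out)
    return out


@dataclass
class TPSModel:
    """A fitted thin-plate spline mapping dim-D points to dim-D points."""

    control_points: np.ndarray  # (n, dim) source points, mm
    weights: np.ndarray  # (n, dim) kernel weights per output component
    affine: np.ndarray  # (dim + 1, dim): row 0 = a1, rows 1.. = linear part
    dim: int
    kernel: str = "r2logr2"

    def transform(self, points: np.ndarray) -> np.ndarray:
        """Map points (m, dim) or (m, 3); extra coordinates pass through."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        if pts.shape[1] < self.dim:
            raise ValueError(
                f"points have {pts.shape[1]} coordinates, model needs {self.dim}"
            )
        core = pts[:, : self.dim]
        out = np.empty_like(core)
        for start in range(0, len(core), _EVAL_CHUNK):
            sl = slice(start, start + _EVAL_CHUNK)
            A = kernel_U(cdist(core[sl], self.control_points), self.kernel)
            out[sl] = (
                self.affine[0]
                + core[sl] @ self.affine[1:]
                + A @ self.weights
            )
        if pts.shape[1] > self.dim:
            out = np.hstack([out, pts[:, self.dim :]])
        return out


def _as_points(obj) -> np.ndarray:
    if isinstance(obj, LandmarkSet):
        return obj.points
    return np.atleast_2d(np.asarray(obj, dtype=np.float64))


def _infer_dim(src: np.ndarray, dst: np.ndarray) -> int:
    if np.ptp(src[:, 2]) == 0 and np.ptp(dst[:, 2]) == 0:
        return 2
    return 3


def fit_tps(
    source: LandmarkSet | np.ndarray,
    destination: LandmarkSet | np.ndarray,
    *,
    dim: int | None = None,
    kernel: str = "r2logr2",
    ridge: float = 0.0,
) -> TPSModel:
    """Fit a TPS interpolating ``source[i] → destination[i]``.

    Requires equal counts n ≥ dim + 1, non-degenerate source geometry (not
    all collinear in 2-D / coplanar in 3-D) and distinct source points;
    sources closer than 1e-6 mm are merged by averaging their destinations
    (with a warning).  ``ridge`` adds λ to K's diagonal for approximating
    splines (default 0 = exact interpolation).
    """
    src = _as_points(source)
    dst = _as_points(destination)
    if src.shape[0] != dst.shape[0]:
        raise ValueError(
            f"source has {src.shape[0]} points but destination has {dst.shape[0]}"
        )
    if dim is None:
        dim = _infer_dim(src, dst) if src.shape[1] == 3 else src.shape[1]
    if dim not in (2, 3):
        raise ValueError(f"dim must be 2 or 3, got {dim}")
    src = src[:, :dim].astype(np.float64)
    dst = dst[:, :dim].astype(np.float64)

    # merge near-duplicate source points (singular L otherwise)
    tree = cKDTree(src)
    dup = tree.query_pairs(_DUPLICATE_TOL, output_type="ndarray")
    if len(dup):
        parent = np.arange(len(src))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, j in dup:
            parent[find(j)] = find(i)
        roots = np.array([find(i) for i in range(len(src))])
        keep = np.unique(roots)
        merged_dst = np.stack([dst[roots == r].mean(axis=0) for r in keep])
        logger.warning(
            "fit_tps: merged %d duplicate source points", len(src) - len(keep)
        )
        src = src[keep]
        dst = merged_dst

    n = len(src)
    if n < dim + 1:
        raise ValueError(f"need at least dim + 1 = {dim + 1} control points, got {n}")
    centered = src - src.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(src).max())) < dim:
        shape = "collinear" if dim == 2 else "coplanar (or collinear)"
        raise ValueError(
            f"degenerate control-point geometry: source points are {shape}"
        )

    K = kernel_U(cdist(src, src), kernel)
    if ridge:
        K = K + ridge * np.eye(n)
    P = np.hstack([np.ones((n, 1)), src])
    L = np.zeros((n + dim + 1, n + dim + 1))
    L[:n, :n] = K
    L[:n, n:] = P
    L[n:, :n] = P.T
    Y = np.zeros((n + dim + 1, dim))
    Y[:n] = dst
    try:
        sol = linalg.solve(L, Y)
    except linalg.LinAlgError as exc:
        raise ValueError(f"singular TPS system (degenerate geometry): {exc}") from exc
    if not np.all(np.isfinite(sol)):
        raise ValueError("TPS solve produced non-finite coefficients")
    return TPSModel(
        control_points=src,
        weights=sol[:n],
        affine=sol[n:],
        dim=dim,
        kernel=kernel,
    )


def evaluate_tps(model: TPSModel, point: np.ndarray) -> np.ndarray:
    """Evaluate the fitted map at one point or an (m, dim) array of points."""
    pts = np.asarray(point, dtype=np.float64)
    single = pts.ndim == 1
    out = model.transform(pts)
    return out[0] if single else out


def tps_to_field(model: TPSModel, grid: VolumeImage) -> DisplacementField:
    """Dense displacement field on a grid: evaluate(x) − x at every voxel.

    Fitted with source = target landmarks and destination = template
    landmarks, the result is the target→template field that backward
    warping consumes.
    """
    pos = grid.grid_positions().reshape(-1, 3)
    mapped = model.transform(pos)
    disp = (mapped - pos)[:, : model.dim]
    vectors = disp.reshape(grid.dims + (model.dim,))
    return DisplacementField(vectors, spacing=grid.spacing, origin=grid.origin)


def warp_image(
    template: VolumeImage,
    field: DisplacementField,
    fill: float | None = None,
) -> VolumeImage:
    """Backward-warp the template through a displacement field.

    Each output voxel takes the template intensity linearly interpolated at
    (voxel physical coordinate + displacement); samples falling outside the
    template get ``fill`` (default: the template minimum).
    """
    if (field.ncomp == 2) != template.is_2d:
        raise ValueError(
            f"grid mismatch: {field.ncomp}-component field with a "
            f"{'2-D' if template.is_2d else '3-D'} template"
        )
    if fill is None:
        fill = float(template.data.min())
    pos = field.grid_positions().reshape(-1, 3)
    pos[:, : field.ncomp] += field.vectors.reshape(-1, field.ncomp)
    vox = _snap_to_grid(template.physical_to_index(pos), template.dims)
    data = ndimage.map_coordinates(
        template.data, vox.T, order=1, mode="constant", cval=fill
    ).reshape(field.dims)
    return VolumeImage(data, spacing=field.spacing, origin=field.origin)
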