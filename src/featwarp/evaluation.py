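"""Registration accuracy against ground truth.

Errors are the per-voxel magnitudes of the vector difference between the
estimated and the true displacement field (the "subtraction field"),
reported in millimetres.  Evaluation is restricted to a body mask by
default, because TPS extrapolation outside the control-point hull — i.e.
outside the body, where no control points exist — is meaningless and
dominates unmasked statistics.

Marker accuracy is the target-registration-error style residual: the
distance between a marker's true mapped position and its
registration-predicted position, summarised as the fraction of markers
below clinical thresholds (default 2 mm and 10 mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .core_io import DisplacementField, LandmarkSet, VolumeImage

__all__ = ["ErrorReport", "error_field", "summarize", "export_overlay"]

DEFAULT_THRESHOLDS = (2.0, 10.0)  # mm


@dataclass
class ErrorReport:
    """Summary statistics of a displacement-error evaluation."""

    mean_error: float  # mm
    max_error: float  # mm
    n_evaluated: int
    exceedance: dict[float, float] = field(default_factory=dict)  # thr -> fraction >
    marker_errors: np.ndarray | None = None  # per-marker residual, mm
    fraction_markers_below: dict[float, float] | None = None  # thr -> fraction <

    def __post_init__(self) -> None:
        if self.n_evaluated <= 0:
            raise ValueError("n_evaluated must be positive")
        if self.mean_error > self.max_error + 1e-12:
            raise ValueError("mean error cannot exceed max error")
        for frac in self.exceedance.values():
            if not 0.0 <= frac <= 1.0:
                raise ValueError("exceedance fractions must be in [0, 1]")

    def to_dict(self) -> dict:
        out = {
            "mean_error_mm": self.mean_error,
            "max_error_mm": self.max_error,
            "n_evaluated": self.n_evaluated,
            "exceedance": {str(k): v for k, v in self.exceedance.items()},
        }
        if self.marker_errors is not None:
            out["marker_errors_mm"] = list(map(float, self.marker_errors))
            out["fraction_markers_below"] = {
                str(k): v for k, v in (self.fraction_markers_below or {}).items()
            }
        return out


def error_field(
    estimated: DisplacementField,
    truth: DisplacementField,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Per-voxel ‖estimated − truth‖₂ (mm); NaN marks not-evaluated voxels."""
    if estimated.dims != truth.dims or estimated.ncomp != truth.ncomp:
        raise ValueError(
            f"grid mismatch: {estimated.dims}x{estimated.ncomp} vs "
            f"{truth.dims}x{truth.ncomp}"
        )
    if not (
        np.allclose(estimated.spacing, truth.spacing)
        and np.allclose(estimated.origin, truth.origin)
    ):
        raise ValueError("grid mismatch: spacing/origin differ")
    err = np.linalg.norm(estimated.vectors - truth.vectors, axis=-1)
    if mask is not None:
        if mask.shape != err.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match grid {err.shape}"
            )
        err = np.where(mask, err, np.nan)
    return err


def summarize(
    errors: np.ndarray,
    markers_true: LandmarkSet | None = None,
    markers_mapped: LandmarkSet | None = None,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> ErrorReport:
    """Summarise an error field (NaN = not evaluated) and marker residuals.

    ``markers_true`` holds the ground-truth-mapped marker positions and
    ``markers_mapped`` the registration-mapped ones; the per-marker residual
    is their pointwise distance.
    """
    vals = np.asarray(errors, dtype=np.float64).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("empty evaluation region (all voxels masked out)")
    exceedance = {
        float(t): float(np.mean(vals > t)) for t in thresholds
    }
    marker_errors = None
    fraction_below = None
    if markers_true is not None or markers_mapped is not None:
        if markers_true is None or markers_mapped is None:
            raise ValueError("both marker sets must be supplied together")
        if len(markers_true) != len(markers_mapped):
            raise ValueError("marker sets must be aligned (equal counts)")
        marker_errors = np.linalg.norm(
            markers_true.points - markers_mapped.points, axis=1
        )
        fraction_below = {
            float(t): float(np.mean(marker_errors < t)) for t in thresholds
        }
    return ErrorReport(
        mean_error=float(vals.mean()),
        max_error=float(vals.max()),
        n_evaluated=int(vals.size),
        exceedance=exceedance,
        marker_errors=marker_errors,
        fraction_markers_below=fraction_below,
    )


def _to_uint8(data: np.ndarray, lo: float, hi: float) -> np.ndarray:
    scaled = np.clip((data - lo) / max(hi - lo, 1e-12), 0.0, 1.0)
    return (scaled * 255).astype(np.uint8)


def _fusion_slice(red: VolumeImage, green: VolumeImage) -> np.ndarray:
    k = red.dims[2] // 2
    r, g = red.data[:, :, k], green.data[:, :, k]
    lo = min(r.min(), g.min())
    hi = max(r.max(), g.max())
    rgb = np.zeros(r.shape + (3,), dtype=np.uint8)
    rgb[..., 0] = _to_uint8(r, lo, hi)
    rgb[..., 1] = _to_uint8(g, lo, hi)
    # transpose so x runs right and y down in the written image
    return rgb.transpose(1, 0, 2)


def export_overlay(
    template: VolumeImage,
    target: VolumeImage,
    warped: VolumeImage,
    out_dir: str | Path,
    prefix: str = "overlay",
) -> dict[str, Path]:
    """Write red/green fusion PNGs of the central slice.

    Target appears in red and template (before) or warped template (after)
    in green; overlapping bright structure shows as yellow.
    """
    if not (template.dims == target.dims == warped.dims):
        raise ValueError("overlay requires images on the same grid")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "before": out_dir / f"{prefix}_before.png",
        "after": out_dir / f"{prefix}_after.png",
    }
    iio.imwrite(paths["before"], _fusion_slice(target, template))
    iio.imwrite(paths["after"], _fusion_slice(target, warped))
    return paths
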