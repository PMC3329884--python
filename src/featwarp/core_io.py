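"""Containers for images, displacement fields and landmarks, plus file I/O.

All registration math runs in physical millimetres.  A voxel index ``v``
(0-based) maps to the physical point ``origin + v * spacing``; direction
cosines other than the identity are rejected on read.  2-D images are carried
as 3-D arrays with a trailing singleton axis and flagged as 2-D so that the
descriptor machinery can switch to its planar mode.

Scalar volumes and vector fields are read and written through SimpleITK
(NIfTI-1 ``.nii``/``.nii.gz`` and MetaImage ``.mha``/``.mhd``).  Landmarks use
a ``label,x,y,z`` CSV dialect or an equivalent JSON document.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

_EDGE_EPS = 1e-6  # voxels


def _snap_to_grid(vox: np.ndarray, dims: tuple[int, ...]) -> np.ndarray:
    """Snap coordinates within round-off of the grid edge onto the edge.

    ``map_coordinates(mode="constant")`` fills for any coordinate strictly
    outside [0, n-1]; without snapping, a numerically-zero displacement can
    turn on-grid boundary samples into fill values.
    """
    for a, n in enumerate(dims[: vox.shape[1]]):
        c = vox[:, a]
        c[(c > -_EDGE_EPS) & (c < 0)] = 0.0
        c[(c > n - 1) & (c < n - 1 + _EDGE_EPS)] = float(n - 1)
    return vox

__all__ = [
    "VolumeImage",
    "DisplacementField",
    "LandmarkSet",
    "ImageFormatError",
    "read_image",
    "write_image",
    "read_field",
    "write_field",
    "read_landmarks",
    "write_landmarks",
]


class ImageFormatError(ValueError):
    """Raised for unreadable files, unsupported formats or pixel types."""


_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _SUPPORTED_SUFFIXES):
        raise ImageFormatError(
            f"unsupported image format {path.suffix!r} for {path}; "
            f"expected one of {_SUPPORTED_SUFFIXES}"
        )


@dataclass
class VolumeImage:
    """A scalar image on a regular, axis-aligned 2-D or 3-D grid.

    Parameters
    ----------
    data
        Intensity array indexed ``[i, j, k]`` along (x, y, z).  2-D images
        are stored with a trailing axis of size 1.
    spacing
        Physical voxel size per axis in millimetres; all components > 0.
    origin
        Physical coordinate of voxel (0, 0, 0) in millimetres.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim == 2:
            self.data = self.data[:, :, np.newaxis]
        if self.data.ndim != 3:
            raise ValueError(f"image data must be 2-D or 3-D, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must have three components")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be positive, got {self.spacing}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def is_2d(self) -> bool:
        """True when the grid is a single slice (third dimension of size 1)."""
        return self.data.shape[2] == 1

    @property
    def ndim_physical(self) -> int:
        return 2 if self.is_2d else 3

    def index_to_physical(self, index: np.ndarray) -> np.ndarray:
        """Physical coordinate(s) (mm) of 0-based voxel index/indices."""
        index = np.asarray(index, dtype=np.float64)
        return np.asarray(self.origin) + index * np.asarray(self.spacing)

    def physical_to_index(self, point: np.ndarray) -> np.ndarray:
        """Continuous voxel index/indices of physical coordinate(s) (mm)."""
        point = np.asarray(point, dtype=np.float64)
        return (point - np.asarray(self.origin)) / np.asarray(self.spacing)

    def grid_positions(self) -> np.ndarray:
        """Physical coordinates of every voxel centre, shape ``dims + (3,)``."""
        idx = np.indices(self.dims, dtype=np.float64)
        pos = np.moveaxis(idx, 0, -1)
        return np.asarray(self.origin) + pos * np.asarray(self.spacing)

    def sample(self, points: np.ndarray, fill: float | None = None,
               order: int = 1) -> np.ndarray:
        """Interpolate intensities at physical points (n, 3).

        ``order`` is the spline order (1 = linear, 3 = cubic).
        """
        if fill is None:
            fill = float(self.data.min())
        vox = _snap_to_grid(self.physical_to_index(np.atleast_2d(points)),
                            self.dims)
        return ndimage.map_coordinates(
            self.data, vox.T, order=order, mode="constant", cval=fill
        )


@dataclass
class DisplacementField:
    """Dense per-voxel displacement vectors (mm, physical coordinates).

    The displacement maps a point in the TARGET grid to its corresponding
    location in the template (backward-warping convention).  The field lives
    on the same grid/spacing/origin as its associated :class:`VolumeImage`;
    2-D fields carry 2 components per voxel, 3-D fields carry 3.
    """

    vectors: np.ndarray  # (nx, ny, nz, ncomp)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 4 or self.vectors.shape[3] not in (2, 3):
            raise ValueError(
                "vectors must have shape (nx, ny, nz, ncomp) with ncomp in {2, 3}, "
                f"got {self.vectors.shape}"
            )
        if self.vectors.shape[3] == 2 and self.vectors.shape[2] != 1:
            raise ValueError("2-component fields must live on a single-slice grid")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement field contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be positive, got {self.spacing}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]

    @property
    def ncomp(self) -> int:
        return self.vectors.shape[3]

    def same_grid(self, other: "DisplacementField | VolumeImage") -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def grid_positions(self) -> np.ndarray:
        idx = np.indices(self.dims, dtype=np.float64)
        pos = np.moveaxis(idx, 0, -1)
        return np.asarray(self.origin) + pos * np.asarray(self.spacing)

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Linearly interpolate the field at physical points (n, 3) → (n, ncomp)."""
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        vox = (points - np.asarray(self.origin)) / np.asarray(self.spacing)
        out = np.empty((points.shape[0], self.ncomp))
        for c in range(self.ncomp):
            out[:, c] = ndimage.map_coordinates(
                self.vectors[..., c], vox.T, order=1, mode="nearest"
            )
        return out


@dataclass
class LandmarkSet:
    """An ordered list of physical points (mm) with optional unique labels."""

    points: np.ndarray  # (n, 3)
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        if self.points.size == 0:
            self.points = self.points.reshape(0, 3)
        if self.points.shape[1] == 2:  # planar points get z = 0
            self.points = np.hstack([self.points, np.zeros((len(self.points), 1))])
        if self.points.shape[1] != 3:
            raise ValueError(f"points must be (n, 3), got {self.points.shape}")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("landmark coordinates must be finite")
        if self.labels is not None:
            self.labels = [str(x) for x in self.labels]
            if len(self.labels) != len(self.points):
                raise ValueError("label count must match point count")
            if len(set(self.labels)) != len(self.labels):
                raise ValueError("labels must be unique")

    def __len__(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# image / field I/O


def _direction_is_identity(direction: tuple[float, ...], dim: int) -> bool:
    return np.allclose(np.asarray(direction).reshape(dim, dim), np.eye(dim), atol=1e-6)


def _read_sitk(path: str | Path) -> sitk.Image:
    path = Path(path)
    if not path.exists():
        raise ImageFormatError(f"no such image file: {path}")
    _check_suffix(path)
    try:
        return sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover - exercised via bad files
        raise ImageFormatError(f"could not read image {path}: {exc}") from exc


def read_image(path: str | Path) -> VolumeImage:
    """Read a scalar NIfTI or MetaImage volume.

    Header spacing/origin are preserved; intensities are kept as stored (any
    slope/intercept rescale is applied by the reader itself).  Single-slice
    inputs come back with ``dims = (nx, ny, 1)`` and are flagged 2-D.
    """
    img = _read_sitk(path)
    if img.GetNumberOfComponentsPerPixel() != 1:
        raise ImageFormatError(
            f"{path}: expected a scalar image, got "
            f"{img.GetNumberOfComponentsPerPixel()} components per pixel"
        )
    dim = img.GetDimension()
    if dim not in (2, 3):
        raise ImageFormatError(f"{path}: unsupported dimension {dim}")
    if not _direction_is_identity(img.GetDirection(), dim):
        raise ImageFormatError(
            f"{path}: non-identity direction cosines are not supported"
        )
    arr = sitk.GetArrayFromImage(img)  # [z, y, x] or [y, x]
    spacing = img.GetSpacing()
    origin = img.GetOrigin()
    if dim == 2:
        arr = arr.T[:, :, np.newaxis]
        spacing = (*spacing, 1.0)
        origin = (*origin, 0.0)
    else:
        arr = arr.transpose(2, 1, 0)
    return VolumeImage(arr, spacing=spacing, origin=origin)


def write_image(image: VolumeImage, path: str | Path) -> None:
    """Write a scalar volume (2-D images are stored as single-slice 3-D)."""
    path = Path(path)
    _check_suffix(path)
    img = sitk.GetImageFromArray(image.data.transpose(2, 1, 0))
    img.SetSpacing(image.spacing)
    img.SetOrigin(image.origin)
    try:
        sitk.WriteImage(img, str(path))
    except RuntimeError as exc:
        raise IOError(f"could not write image {path}: {exc}") from exc


def write_field(field: DisplacementField, path: str | Path) -> None:
    """Write a displacement field as a multi-component vector volume."""
    path = Path(path)
    _check_suffix(path)
    arr = field.vectors.transpose(2, 1, 0, 3)
    img = sitk.GetImageFromArray(arr, isVector=True)
    img.SetSpacing(field.spacing)
    img.SetOrigin(field.origin)
    try:
        sitk.WriteImage(img, str(path))
    except RuntimeError as exc:
        raise IOError(f"could not write field {path}: {exc}") from exc


def read_field(path: str | Path) -> DisplacementField:
    """Read a vector volume written by :func:`write_field`."""
    img = _read_sitk(path)
    ncomp = img.GetNumberOfComponentsPerPixel()
    if ncomp not in (2, 3):
        raise ImageFormatError(
            f"{path}: expected a 2- or 3-component vector image, got {ncomp}"
        )
    if not _direction_is_identity(img.GetDirection(), img.GetDimension()):
        raise ImageFormatError(
            f"{path}: non-identity direction cosines are not supported"
        )
    arr = sitk.GetArrayFromImage(img)  # [z, y, x, c]
    if arr.ndim == 3:  # 2-D image on disk
        arr = arr.transpose(1, 0, 2)[:, :, np.newaxis, :]
        spacing = (*img.GetSpacing(), 1.0)
        origin = (*img.GetOrigin(), 0.0)
    else:
        arr = arr.transpose(2, 1, 0, 3)
        spacing = img.GetSpacing()
        origin = img.GetOrigin()
    return DisplacementField(arr, spacing=spacing, origin=origin)


# ---------------------------------------------------------------------------
# landmark I/O

_CSV_HEADER = ["label", "x", "y", "z"]


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    """Write landmarks as ``label,x,y,z`` CSV or as JSON (.json suffix)."""
    path = Path(path)
    labels = landmarks.labels
    if path.suffix.lower() == ".json":
        doc = {"labels": labels, "points": landmarks.points.tolist()}
        path.write_text(json.dumps(doc, indent=1))
        return
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_HEADER)
        for i, p in enumerate(landmarks.points):
            label = labels[i] if labels is not None else ""
            writer.writerow([label, repr(float(p[0])), repr(float(p[1])),
                             repr(float(p[2]))])


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read landmarks from CSV (``label,x,y,z``) or JSON.

    Malformed CSV rows raise a :class:`ValueError` naming the line number.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text())
        points = np.asarray(doc["points"], dtype=np.float64).reshape(-1, 3)
        return LandmarkSet(points, labels=doc.get("labels"))
    points: list[list[float]] = []
    labels: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if lineno == 1:
                if [c.strip().lower() for c in row] != _CSV_HEADER:
                    raise ValueError(
                        f"{path}: line 1: expected header {','.join(_CSV_HEADER)!r}"
                    )
                continue
            if not row:
                continue
            if len(row) != 4:
                raise ValueError(
                    f"{path}: line {lineno}: expected 4 fields, got {len(row)}"
                )
            try:
                points.append([float(row[1]), float(row[2]), float(row[3])])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric coordinate in {row!r}"
                ) from exc
            labels.append(row[0])
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    if all(lb == "" for lb in labels):
        return LandmarkSet(pts)
    return LandmarkSet(pts, labels=labels)
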