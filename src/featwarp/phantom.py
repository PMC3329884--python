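"""Digital deformation phantoms with analytically known ground truth.

The registration method is validated on synthetic CT-like phantoms: a
bounded elliptical/ellipsoidal "body" (soft tissue, ~40 HU) on an air
background (−1000 HU), filled with a smooth random blob texture so that
gradient features are detectable everywhere inside the body, optionally with
embedded bright spherical markers (bone-like inserts of known position, the
digital analogue of the rigid tumour-simulating balls used in physical
deformable phantoms).

Deformations with exact ground truth:

* :class:`HarmonicDeformation` — the planar harmonic warp
  x′(x, y) = (1 + b·cos(m·q))·x with q = atan2(y, x) measured about a
  centre; ``m`` sets the angular complexity and ``b`` the magnitude of the
  deformation, and only the x coordinate moves.
* :class:`GaussianLobeDeformation` — a smooth 3-D field built from a few
  Gaussian-windowed displacement lobes, standing in for respiratory-scale
  motion (default peak ≈ 18 mm, mirroring a 1.8 cm tumour excursion).
* :class:`TranslationDeformation` — a rigid shift, handy for exact-recovery
  checks.

``deform_phantom`` resamples the template through the numerically inverted
map and stores the ground-truth displacement field in the TARGET frame with
the same target→template convention as registration output, so estimated
and true fields are directly comparable by subtraction, and markers are
transported analytically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq

from .core_io import DisplacementField, LandmarkSet, VolumeImage

__all__ = [
    "HarmonicDeformation",
    "GaussianLobeDeformation",
    "TranslationDeformation",
    "Marker",
    "PhantomSpec",
    "harmonic_displace",
    "body_mask",
    "generate_phantom",
    "random_markers",
    "deform_phantom",
]

logger = logging.getLogger(__name__)

_INV_TOL = 1e-9  # mm, numerical map-inversion tolerance
_CHUNK = 262_144


@dataclass(frozen=True)
class HarmonicDeformation:
    """Planar harmonic warp x′ = (1 + b cos(m q)) x about ``center``.

    ``q = atan2(y, x)`` relative to the centre (q := 0 on the axis itself,
    where the map is the identity anyway); y and z are unchanged.  ``b``
    (|b| < 1) sets the deformation magnitude and the integer ``m ≥ 0`` its
    angular complexity.
    """

    b: float
    m: int
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if abs(self.b) >= 1:
            raise ValueError("|b| must be < 1 to keep the map orientation-preserving")
        if self.m < 0 or int(self.m) != self.m:
            raise ValueError("m must be a non-negative integer")

    def forward(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64)).copy()
        c = np.asarray(self.center[: pts.shape[1]])
        rel = pts - c
        x, y = rel[:, 0], rel[:, 1]
        q = np.arctan2(y, x)  # atan2(0, 0) = 0 by convention
        pts[:, 0] = c[0] + (1.0 + self.b * np.cos(self.m * q)) * x
        return pts

    def inverse(self, points: np.ndarray) -> np.ndarray:
        """Solve x from x′ = (1 + b cos(m·atan2(y, x)))·x per point.

        Vectorised Newton iteration with a bracketed-root fallback;
        converges to < 1e-6 mm.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64)).copy()
        c = np.asarray(self.center[: pts.shape[1]])
        xt = pts[:, 0] - c[0]
        y = pts[:, 1] - c[1]
        if self.m == 0:
            pts[:, 0] = c[0] + xt / (1.0 + self.b)
            return pts
        x = xt.copy()
        for _ in range(80):
            q = np.arctan2(y, x)
            cmq = np.cos(self.m * q)
            smq = np.sin(self.m * q)
            f = x * (1.0 + self.b * cmq) - xt
            if np.max(np.abs(f)) < _INV_TOL:
                break
            r2 = x * x + y * y
            with np.errstate(divide="ignore", invalid="ignore"):
                dq = np.where(r2 > 0, -y / r2, 0.0)
            fp = 1.0 + self.b * cmq - self.b * self.m * x * smq * dq
            fp = np.where(np.abs(fp) < 1e-12, 1.0, fp)
            x = x - f / fp
        q = np.arctan2(y, x)
        bad = np.abs(x * (1.0 + self.b * np.cos(self.m * q)) - xt) > 1e-6
        if np.any(bad):
            ab = abs(self.b)
            for i in np.flatnonzero(bad):
                lo, hi = sorted((xt[i] / (1.0 + ab), xt[i] / (1.0 - ab)))
                yi = y[i]

                def g(xx):
                    return xx * (1.0 + self.b * np.cos(
                        self.m * np.arctan2(yi, xx))) - xt[i]

                x[i] = brentq(g, lo - 1e-9, hi + 1e-9, xtol=_INV_TOL)
        pts[:, 0] = c[0] + x
        return pts


def harmonic_displace(point: np.ndarray, d: HarmonicDeformation) -> np.ndarray:
    """Displace a single physical point (2- or 3-vector) harmonically."""
    pt = np.asarray(point, dtype=np.float64)
    return d.forward(pt[np.newaxis, :])[0]


@dataclass(frozen=True)
class TranslationDeformation:
    """Rigid shift by ``t`` (mm)."""

    t: tuple[float, float, float]

    def forward(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return pts + np.asarray(self.t)[: pts.shape[1]]

    def inverse(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return pts - np.asarray(self.t)[: pts.shape[1]]


@dataclass(frozen=True)
class GaussianLobeDeformation:
    """Sum of Gaussian-windowed displacement lobes (smooth 3-D field).

    d(x) = Σ_l a_l · exp(−|x − c_l|² / 2σ²); forward map x ↦ x + d(x).
    Invertible as long as the displacement gradient stays below 1, i.e.
    lobe amplitudes are small relative to the length scale σ.
    """

    centers: np.ndarray  # (L, 3) mm
    amplitudes: np.ndarray  # (L, 3) mm
    sigma: float  # mm

    def __post_init__(self) -> None:
        object.__setattr__(self, "centers",
                           np.atleast_2d(np.asarray(self.centers, dtype=np.float64)))
        object.__setattr__(self, "amplitudes",
                           np.atleast_2d(np.asarray(self.amplitudes, dtype=np.float64)))
        if self.centers.shape != self.amplitudes.shape or self.centers.shape[1] != 3:
            raise ValueError("centers and amplitudes must both be (L, 3)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def displacement(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        out = np.zeros_like(pts)
        for start in range(0, len(pts), _CHUNK):
            sl = slice(start, start + _CHUNK)
            d2 = (
                np.sum(pts[sl] ** 2, axis=1)[:, None]
                - 2.0 * pts[sl] @ self.centers.T
                + np.sum(self.centers**2, axis=1)[None, :]
            )
            w = np.exp(-d2 / (2.0 * self.sigma**2))
            out[sl] = w @ self.amplitudes
        return out

    def forward(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return pts + self.displacement(pts)

    def inverse(self, points: np.ndarray) -> np.ndarray:
        """Fixed-point inversion x_{n+1} = x′ − d(x_n); errors if it stalls."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        x = pts.copy()
        for _ in range(200):
            step = pts - self.displacement(x) - x
            x += step
            if np.max(np.abs(step)) < _INV_TOL:
                return x
        raise ValueError(
            "fixed-point inversion did not converge: the requested field is "
            "too strong to invert (reduce amplitude or increase sigma)"
        )

    def max_gradient_estimate(self) -> float:
        """Sampled estimate of the largest displacement-gradient norm.

        Central finite differences of d on a coarse grid covering the lobes
        (±3σ around the centres); the Frobenius norm of the Jacobian bounds
        its spectral norm, so values < 1 imply an invertible forward map on
        the sampled region.
        """
        lo = self.centers.min(axis=0) - 3.0 * self.sigma
        hi = self.centers.max(axis=0) + 3.0 * self.sigma
        axes = [np.linspace(lo[a], hi[a], 14) for a in range(3)]
        pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        h = 0.05 * self.sigma
        j2 = np.zeros(len(pts))
        for a in range(3):
            e = np.zeros(3)
            e[a] = h
            deriv = (self.displacement(pts + e) - self.displacement(pts - e)) / (2 * h)
            j2 += np.sum(deriv * deriv, axis=1)
        return float(np.sqrt(j2.max()))

    @classmethod
    def random(
        cls,
        rng: np.random.Generator,
        region_center: np.ndarray,
        region_semiaxes: np.ndarray,
        *,
        n_lobes: int = 6,
        sigma: float = 45.0,
        peak: float = 18.0,
    ) -> "GaussianLobeDeformation":
        """Random lobes inside a region, rescaled to a given peak |d| (mm)."""
        center = np.asarray(region_center, dtype=np.float64)
        semi = np.asarray(region_semiaxes, dtype=np.float64)
        centers = center + rng.uniform(-0.6, 0.6, size=(n_lobes, 3)) * semi
        amps = rng.normal(size=(n_lobes, 3))
        deform = cls(centers, amps, sigma)
        # normalise the peak displacement over a sample of body points
        u = rng.normal(size=(4096, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        radii = rng.uniform(0, 1, size=(4096, 1)) ** (1 / 3)
        sample = center + u * radii * semi
        mags = np.linalg.norm(deform.displacement(sample), axis=1)
        scale = peak / max(mags.max(), 1e-12)
        return cls(centers, amps * scale, sigma)


# ---------------------------------------------------------------------------
# phantom generation


@dataclass(frozen=True)
class Marker:
    """A spherical insert: centre (mm), radius (mm) and intensity contrast."""

    center: tuple[float, float, float]
    radius: float
    contrast: float


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, texture and marker layout of a synthetic phantom.

    Intensities are CT-like: air background (−1000), a soft-tissue body
    (~40) textured by smooth random Gaussian blobs, bright bone-like
    nodules ringing the periphery (rib cross-sections in an axial slice),
    and optional bright spherical markers.  Real anatomy is neither
    perfectly elliptical nor single-scale, so the body contour is an
    ellipse with a small smooth radial perturbation
    (``boundary_amplitude`` as a fraction of the local radius) and blob
    widths are drawn from [0.5, 1.5] × ``texture_scale``; together with
    the rib ring these keep the contour and texture from being
    artificially self-similar.  A fixed ``seed`` makes the phantom
    byte-identical across calls.
    """

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    body_center: tuple[float, float, float] | None = None
    body_semiaxes: tuple[float, float, float] = (60.0, 70.0, 65.0)
    boundary_amplitude: float = 0.05
    background: float = -1000.0
    body_intensity: float = 40.0
    texture_blobs: int = 300
    texture_amplitude: float = 250.0
    texture_scale: float = 8.0  # mm
    bone_features: int = 14
    bone_contrast: float = 700.0
    bone_radius_range: tuple[float, float] = (2.5, 6.0)  # mm
    smooth_sigma: float = 0.7  # voxels
    markers: tuple[Marker, ...] = ()
    seed: int = 0

    @property
    def is_2d(self) -> bool:
        return self.dims[2] == 1

    def center(self) -> np.ndarray:
        if self.body_center is not None:
            return np.asarray(self.body_center, dtype=np.float64)
        return (np.asarray(self.dims) - 1) * np.asarray(self.spacing) / 2.0


def _grid_positions(spec: PhantomSpec) -> np.ndarray:
    idx = np.indices(spec.dims, dtype=np.float64)
    return np.moveaxis(idx, 0, -1) * np.asarray(spec.spacing)


def _ellipsoid_value(pos: np.ndarray, center: np.ndarray, semi: np.ndarray,
                     is_2d: bool) -> np.ndarray:
    rel = (pos - center) / semi
    if is_2d:
        rel = rel[..., :2]
    return np.sum(rel * rel, axis=-1)


def _boundary_profile(spec: PhantomSpec):
    """Seeded smooth radial perturbation of the body contour.

    Returns ``(wavevectors, phases, amplitudes)`` of a low-frequency cosine
    sum over unit directions, scaled so its peak equals
    ``boundary_amplitude``; ``None`` when the amplitude is zero.
    """
    if spec.boundary_amplitude == 0:
        return None
    rng = np.random.default_rng([spec.seed, 23])
    dim = 2 if spec.is_2d else 3
    n_waves = 8
    dirs = rng.normal(size=(n_waves, dim))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    wavevec = dirs * rng.uniform(3.0, 9.0, size=(n_waves, 1))
    phases = rng.uniform(0.0, 2.0 * np.pi, n_waves)
    amps = rng.normal(size=n_waves)
    probe = rng.normal(size=(2048, dim))
    probe /= np.linalg.norm(probe, axis=1, keepdims=True)
    peak = np.abs(np.cos(probe @ wavevec.T + phases) @ amps).max()
    return wavevec, phases, amps * (spec.boundary_amplitude / peak)


def _radius_threshold(rel: np.ndarray, profile) -> np.ndarray:
    """Perturbed body radius (in normalised ellipse coordinates)."""
    if profile is None:
        return np.ones(rel.shape[:-1])
    wavevec, phases, amps = profile
    r = np.linalg.norm(rel, axis=-1, keepdims=True)
    u = np.divide(rel, r, out=np.zeros_like(rel), where=r > 0)
    return 1.0 + np.cos(u @ wavevec.T + phases) @ amps


def _inside_body(pos: np.ndarray, spec: PhantomSpec, profile) -> np.ndarray:
    center = spec.center()
    semi = np.asarray(spec.body_semiaxes, dtype=np.float64)
    rel = (pos - center) / semi
    if spec.is_2d:
        rel = rel[..., :2]
    r = np.linalg.norm(rel, axis=-1)
    return r <= _radius_threshold(rel, profile)


def body_mask(spec: PhantomSpec) -> np.ndarray:
    """Boolean in-body mask of the phantom's (perturbed) elliptical body."""
    return _inside_body(_grid_positions(spec), spec, _boundary_profile(spec))


def generate_phantom(spec: PhantomSpec) -> tuple[VolumeImage, LandmarkSet]:
    """Render the phantom; returns the image and the marker centres (mm).

    Deterministic given ``spec.seed``.  Raises if any marker sphere is not
    fully inside the body.
    """
    rng = np.random.default_rng(spec.seed)
    center = spec.center()
    semi = np.asarray(spec.body_semiaxes, dtype=np.float64)
    profile = _boundary_profile(spec)
    pos = _grid_positions(spec)
    mask = _inside_body(pos, spec, profile)

    data = np.full(spec.dims, spec.background, dtype=np.float64)
    data[mask] = spec.body_intensity

    # smooth random blob texture inside the body (multi-scale widths)
    spacing = np.asarray(spec.spacing)
    n_placed = 0
    while n_placed < spec.texture_blobs:
        cand = center + rng.uniform(-1, 1, size=3) * semi
        if spec.is_2d:
            cand[2] = 0.0
        amp = rng.normal(0.0, spec.texture_amplitude)
        sigma_mm = spec.texture_scale * rng.uniform(0.5, 1.5)
        if not _inside_body(cand[np.newaxis, :], spec, profile)[0]:
            continue
        n_placed += 1
        # truncated local support, 3.5 sigma
        lo = np.maximum(np.floor((cand - 3.5 * sigma_mm) / spacing), 0).astype(int)
        hi = np.minimum(
            np.ceil((cand + 3.5 * sigma_mm) / spacing) + 1, spec.dims
        ).astype(int)
        if spec.is_2d:
            lo[2], hi[2] = 0, 1
        sub = tuple(slice(lo[a], hi[a]) for a in range(3))
        d2 = np.sum((pos[sub] - cand) ** 2, axis=-1)
        data[sub] += np.where(
            mask[sub], amp * np.exp(-d2 / (2.0 * sigma_mm**2)), 0.0
        )

    # bone-like nodules around the periphery (rib cross-sections); spread
    # quasi-evenly in direction with jitter so the ring is irregular but
    # covers the whole contour
    for bi in range(spec.bone_features):
        if spec.is_2d:
            theta = 2.0 * np.pi * (bi + 0.35 * rng.uniform(-1, 1)) / spec.bone_features
            u = np.array([np.cos(theta), np.sin(theta)])
        else:
            # Fibonacci-lattice direction plus jitter
            ga = np.pi * (3.0 - np.sqrt(5.0))
            z = 1.0 - 2.0 * (bi + 0.5) / spec.bone_features
            rxy = np.sqrt(max(1.0 - z * z, 0.0))
            theta = ga * bi + 0.5 * rng.uniform(-1, 1)
            u = np.array([rxy * np.cos(theta), rxy * np.sin(theta), z])
            u += 0.15 * rng.normal(size=3)
            u /= np.linalg.norm(u)
        frac = rng.uniform(0.76, 0.90)
        thr = _radius_threshold(u[np.newaxis, :], profile)[0]
        rel = frac * thr * u
        bc = center.copy()
        bc[: rel.size] = center[: rel.size] + rel * semi[: rel.size]
        if spec.is_2d:
            bc[2] = 0.0
        br = rng.uniform(*spec.bone_radius_range)
        lo = np.maximum(np.floor((bc - br) / spacing) - 1, 0).astype(int)
        hi = np.minimum(np.ceil((bc + br) / spacing) + 2, spec.dims).astype(int)
        if spec.is_2d:
            lo[2], hi[2] = 0, 1
        sub = tuple(slice(lo[a], hi[a]) for a in range(3))
        if spec.is_2d:
            d2 = np.sum((pos[sub][..., :2] - bc[:2]) ** 2, axis=-1)
        else:
            d2 = np.sum((pos[sub] - bc) ** 2, axis=-1)
        data[sub] = np.where(
            d2 <= br * br, spec.body_intensity + spec.bone_contrast, data[sub]
        )

    # spherical markers (rigid bright inserts)
    points = []
    for mk in spec.markers:
        mc = np.asarray(mk.center, dtype=np.float64)
        shrunk = np.maximum(semi - mk.radius, 1e-9)
        if np.sqrt(_ellipsoid_value(mc, center, shrunk, spec.is_2d)) > (
            1.0 - spec.boundary_amplitude
        ):
            raise ValueError(
                f"marker at {mk.center} (radius {mk.radius} mm) is not fully "
                "inside the body"
            )
        lo = np.maximum(np.floor((mc - mk.radius) / spacing) - 1, 0).astype(int)
        hi = np.minimum(np.ceil((mc + mk.radius) / spacing) + 2, spec.dims).astype(int)
        if spec.is_2d:
            lo[2], hi[2] = 0, 1
        sub = tuple(slice(lo[a], hi[a]) for a in range(3))
        d2 = np.sum((pos[sub] - mc) ** 2, axis=-1)
        if spec.is_2d:
            d2 = np.sum((pos[sub][..., :2] - mc[:2]) ** 2, axis=-1)
        data[sub] = np.where(
            d2 <= mk.radius**2, spec.body_intensity + mk.contrast, data[sub]
        )
        points.append(mc)

    if spec.smooth_sigma > 0:
        sig = (spec.smooth_sigma, spec.smooth_sigma,
               0.0 if spec.is_2d else spec.smooth_sigma)
        data = ndimage.gaussian_filter(data, sigma=sig)

    image = VolumeImage(data, spacing=spec.spacing, origin=(0.0, 0.0, 0.0))
    pts = np.asarray(points).reshape(-1, 3)
    labels = [f"marker{i:03d}" for i in range(len(pts))]
    return image, LandmarkSet(pts, labels=labels if len(pts) else None)


def random_markers(
    spec: PhantomSpec,
    n: int,
    *,
    radius_range: tuple[float, float] = (5.0, 10.0),
    contrast_range: tuple[float, float] = (600.0, 1400.0),
    rng: np.random.Generator | None = None,
    margin: float = 0.75,
    min_separation: float = 20.0,
    max_tries: int = 20_000,
) -> tuple[Marker, ...]:
    """Draw n non-overlapping marker positions inside the body.

    Marker radii and contrasts are drawn per marker from the given ranges
    (rigid inserts of varying density and size), which also keeps the
    markers mutually distinguishable for the descriptor matcher.
    ``margin`` shrinks the admissible region (fraction of the body
    semi-axes) so markers stay away from the body edge.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    center = spec.center()
    semi = np.asarray(spec.body_semiaxes, dtype=np.float64) * margin
    placed: list[np.ndarray] = []
    sizes: list[float] = []
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} markers with separation "
                f"{min_separation} mm; relax the layout parameters"
            )
        cand = center + rng.uniform(-1, 1, size=3) * semi
        if spec.is_2d:
            cand[2] = 0.0
        if _ellipsoid_value(cand, center, semi, spec.is_2d) > 1.0:
            continue
        if placed and np.min(
            np.linalg.norm(np.stack(placed) - cand, axis=1)
        ) < min_separation:
            continue
        placed.append(cand)
        sizes.append(float(rng.uniform(*radius_range)))
    return tuple(
        Marker(tuple(map(float, p)), r, float(rng.uniform(*contrast_range)))
        for p, r in zip(placed, sizes)
    )


def deform_phantom(
    image: VolumeImage,
    markers: LandmarkSet,
    deformation,
    *,
    fill: float | None = None,
    order: int = 3,
) -> tuple[VolumeImage, LandmarkSet, DisplacementField]:
    """Apply a known deformation: target image, moved markers, ground truth.

    The target is the phantom resampled through the numerically inverted
    map (backward sampling); the ground-truth displacement field lives on
    the target grid in the target→template convention, so it is directly
    comparable with registration output; markers are moved analytically by
    the forward map.
    """
    if isinstance(deformation, GaussianLobeDeformation):
        g = deformation.max_gradient_estimate()
        if g >= 1.0:
            raise ValueError(
                f"requested field is not invertible (displacement-gradient "
                f"bound {g:.2f} >= 1)"
            )
    positions = image.grid_positions().reshape(-1, 3)
    src = np.empty_like(positions)
    for start in range(0, len(positions), _CHUNK):
        sl = slice(start, start + _CHUNK)
        src[sl] = deformation.inverse(positions[sl])
    target_data = image.sample(src, fill=fill, order=order).reshape(image.dims)
    target = VolumeImage(target_data, spacing=image.spacing, origin=image.origin)

    ncomp = 2 if image.is_2d else 3
    truth = DisplacementField(
        (src - positions)[:, :ncomp].reshape(image.dims + (ncomp,)),
        spacing=image.spacing,
        origin=image.origin,
    )
    moved = deformation.forward(markers.points) if len(markers) else markers.points
    displaced = LandmarkSet(np.asarray(moved).reshape(-1, 3), labels=markers.labels)
    return target, displaced, truth
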