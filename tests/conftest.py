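"""Shared fixtures and independent reference (oracle) implementations.

The oracles are deliberately naive scalar loops, written directly from the
method's definitions, so they stay independent of the vectorised library
code they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from featwarp import PhantomSpec, VolumeImage, generate_phantom


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def random_volume(rng) -> VolumeImage:
    return VolumeImage(
        rng.normal(size=(12, 11, 10)),
        spacing=(1.5, 1.0, 2.0),
        origin=(5.0, -3.0, 2.0),
    )


@pytest.fixture
def small_phantom_2d():
    spec = PhantomSpec(
        dims=(64, 64, 1),
        spacing=(2.0, 2.0, 1.0),
        body_semiaxes=(50.0, 55.0, 1.0),
        texture_blobs=150,
        texture_scale=6.0,
        bone_features=8,
        seed=7,
    )
    image, markers = generate_phantom(spec)
    return spec, image, markers


@pytest.fixture
def small_phantom_3d():
    spec = PhantomSpec(
        dims=(48, 48, 48),
        spacing=(2.0, 2.0, 2.0),
        body_semiaxes=(38.0, 40.0, 42.0),
        texture_blobs=250,
        texture_scale=7.0,
        bone_features=16,
        seed=11,
    )
    image, markers = generate_phantom(spec)
    return spec, image, markers


# ---------------------------------------------------------------------------
# oracle implementations


def oracle_gradient(data: np.ndarray, i: int, j: int, k: int) -> tuple:
    """Central difference with replicated-edge neighbours, one voxel."""
    nx, ny, nz = data.shape

    def at(a, b, c):
        return data[min(max(a, 0), nx - 1),
                    min(max(b, 0), ny - 1),
                    min(max(c, 0), nz - 1)]

    gx = 0.5 * (at(i + 1, j, k) - at(i - 1, j, k))
    gy = 0.5 * (at(i, j + 1, k) - at(i, j - 1, k))
    gz = 0.0 if nz == 1 else 0.5 * (at(i, j, k + 1) - at(i, j, k - 1))
    return gx, gy, gz


def oracle_descriptor(image: VolumeImage, index: tuple) -> np.ndarray:
    """Triple-loop 192-component orientation histogram (3-D mode)."""
    values = np.zeros(192)
    ci, cj, ck = index
    for ox in range(-4, 4):
        for oy in range(-4, 4):
            for oz in range(-4, 4):
                g = oracle_gradient(image.data, ci + ox, cj + oy, ck + oz)
                quad = ((ox >= 0) << 2) | ((oy >= 0) << 1) | (oz >= 0)
                for pi, (a, b) in enumerate(((0, 1), (1, 2), (0, 2))):
                    ga, gb = g[a], g[b]
                    mag = math.hypot(ga, gb)
                    ang = math.degrees(math.atan2(gb, ga)) % 360.0
                    values[quad * 24 + pi * 8 + (int(ang // 45.0) % 8)] += mag
    return values


def oracle_descriptor_2d(image: VolumeImage, index: tuple) -> np.ndarray:
    """Double-loop 32-component planar histogram (2-D mode)."""
    values = np.zeros(32)
    ci, cj, _ = index
    for ox in range(-4, 4):
        for oy in range(-4, 4):
            gx, gy, _ = oracle_gradient(image.data, ci + ox, cj + oy, 0)
            quad = ((ox >= 0) << 1) | (oy >= 0)
            mag = math.hypot(gx, gy)
            ang = math.degrees(math.atan2(gy, gx)) % 360.0
            values[quad * 8 + (int(ang // 45.0) % 8)] += mag
    return values


def oracle_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Scalar-loop sum of squared component differences."""
    total = 0.0
    for x, y in zip(a, b):
        total += (x - y) ** 2
    return total


def oracle_match(values_a, indices_a, values_b, indices_b, kappa_threshold=0.5):
    """Exhaustive double-loop ratio-test matching.

    Returns ``{template_row: (target_row, s1, s2, kappa)}`` with ties broken
    toward the smaller lexicographic target voxel index.
    """
    out = {}
    for ta in range(len(values_a)):
        scored = []
        for tb in range(len(values_b)):
            scored.append((oracle_distance(values_a[ta], values_b[tb]),
                           tuple(indices_b[tb]), tb))
        if len(scored) < 2:
            continue
        scored.sort()
        s1, _, b1 = scored[0]
        s2 = scored[1][0]
        kappa = 0.0 if s1 == 0.0 else s1 / s2
        if kappa < kappa_threshold:
            out[ta] = (b1, s1, s2, kappa)
    return out


def oracle_tps_eval(point, control_points, weights, affine):
    """Scalar evaluation of the TPS map at one point."""
    dim = len(point)
    out = np.array(affine[0], dtype=float)
    for a in range(dim):
        out += affine[1 + a] * point[a]
    for p, w in zip(control_points, weights):
        r = math.dist(tuple(p), tuple(point))
        if r > 0:
            out += w * (r * r * math.log(r * r))
    return out
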