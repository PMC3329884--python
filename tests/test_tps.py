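"""Thin-plate-spline fitting, evaluation, dense field and warping tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from featwarp import (
    DisplacementField,
    LandmarkSet,
    VolumeImage,
    evaluate_tps,
    fit_tps,
    kernel_U,
    tps_to_field,
    warp_image,
)
from conftest import oracle_tps_eval


class TestKernel:
    def test_values(self):
        assert kernel_U(0.0) == 0.0
        assert kernel_U(1.0) == 0.0
        assert kernel_U(2.0) == pytest.approx(4.0 * np.log(4.0), rel=1e-12)

    def test_array_input_and_continuity_near_zero(self):
        r = np.array([0.0, 1e-12, 1e-6, 1.0])
        out = kernel_U(r)
        assert out[0] == 0.0
        assert abs(out[1]) < 1e-10
        assert out[3] == 0.0

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            kernel_U(-0.5)


class TestFit:
    def test_identity_correspondence(self, rng):
        src = rng.uniform(0, 100, size=(10, 3))
        model = fit_tps(src, src.copy(), dim=3)
        assert np.abs(model.weights).max() < 1e-8
        np.testing.assert_allclose(model.affine[1:], np.eye(3), atol=1e-8)
        pts = rng.uniform(-50, 150, size=(20, 3))
        np.testing.assert_allclose(evaluate_tps(model, pts), pts, atol=1e-6)

    def test_pure_translation(self, rng):
        src = rng.uniform(0, 100, size=(8, 3))
        t = np.array([3.0, -7.0, 1.5])
        model = fit_tps(src, src + t, dim=3)
        assert np.abs(model.weights).max() < 1e-8
        pts = rng.uniform(0, 100, size=(20, 3))
        np.testing.assert_allclose(evaluate_tps(model, pts), pts + t, atol=1e-6)

    def test_affine_destinations_zero_weights(self, rng):
        src = rng.uniform(0, 100, size=(10, 3))
        A = np.eye(3) + 0.1 * rng.normal(size=(3, 3))
        b = rng.normal(size=3) * 10
        model = fit_tps(src, src @ A.T + b, dim=3)
        assert np.abs(model.weights).max() < 1e-8
        pts = rng.uniform(0, 100, size=(100, 3))
        np.testing.assert_allclose(
            evaluate_tps(model, pts), pts @ A.T + b, atol=1e-6
        )

    def test_exact_interpolation_and_side_conditions(self, rng):
        src = rng.uniform(0, 100, size=(15, 3))
        dst = src + rng.normal(size=(15, 3)) * 8
        model = fit_tps(src, dst, dim=3)
        np.testing.assert_allclose(evaluate_tps(model, src), dst, atol=1e-6)
        np.testing.assert_allclose(model.weights.sum(axis=0), 0, atol=1e-8)
        np.testing.assert_allclose(src.T @ model.weights, 0, atol=1e-8)

    def test_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="points"):
            fit_tps(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)), dim=3)

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError, match="at least"):
            fit_tps(rng.normal(size=(3, 3)), rng.normal(size=(3, 3)), dim=3)

    def test_coplanar_sources_rejected(self, rng):
        src = rng.uniform(0, 50, size=(8, 3))
        src[:, 2] = 7.0  # all in one plane
        with pytest.raises(ValueError, match="coplanar"):
            fit_tps(src, src + 1.0, dim=3)

    def test_collinear_2d_sources_rejected(self):
        src = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        with pytest.raises(ValueError, match="collinear"):
            fit_tps(src, src + 1.0, dim=2)

    def test_duplicate_sources_merged(self, rng, caplog):
        src = rng.uniform(0, 50, size=(8, 3))
        src[5] = src[2] + 1e-9
        dst = src + rng.normal(size=(8, 3))
        model = fit_tps(src, dst, dim=3)
        assert len(model.control_points) == 7

    def test_2d_mode_inferred_from_planar_landmarks(self, rng):
        pts = np.hstack([rng.uniform(0, 50, size=(6, 2)), np.zeros((6, 1))])
        dst = pts + [1.0, 2.0, 0.0]
        model = fit_tps(LandmarkSet(pts), LandmarkSet(dst))
        assert model.dim == 2

    @settings(max_examples=20, deadline=None)
    @given(n=st.integers(min_value=5, max_value=25),
           seed=st.integers(min_value=0, max_value=10_000))
    def test_side_conditions_hold_for_random_fits(self, n, seed):
        r = np.random.default_rng(seed)
        src = r.uniform(0, 100, size=(n, 3))
        dst = src + r.normal(size=(n, 3)) * 5
        model = fit_tps(src, dst, dim=3)
        assert np.abs(model.weights.sum(axis=0)).max() < 1e-8
        assert np.abs(src.T @ model.weights).max() < 1e-7


class TestEvaluate:
    def test_matches_scalar_oracle(self, rng):
        src = rng.uniform(0, 100, size=(12, 3))
        dst = src + rng.normal(size=(12, 3)) * 6
        model = fit_tps(src, dst, dim=3)
        for p in rng.uniform(0, 100, size=(10, 3)):
            expected = oracle_tps_eval(
                p, model.control_points,
                model.weights, model.affine,
            )
            np.testing.assert_allclose(evaluate_tps(model, p), expected,
                                       rtol=1e-9, atol=1e-9)

    def test_single_point_returns_vector(self, rng):
        src = rng.uniform(0, 10, size=(5, 3))
        model = fit_tps(src, src, dim=3)
        out = evaluate_tps(model, np.array([1.0, 2.0, 3.0]))
        assert out.shape == (3,)


class TestField:
    def _grid(self):
        return VolumeImage(np.zeros((6, 7, 5)), spacing=(2.0, 1.5, 3.0),
                           origin=(1.0, 0.0, -2.0))

    def test_identity_model_zero_field(self, rng):
        src = rng.uniform(0, 10, size=(6, 3))
        field = tps_to_field(fit_tps(src, src, dim=3), self._grid())
        np.testing.assert_allclose(field.vectors, 0, atol=1e-8)

    def test_translation_model_constant_field(self, rng):
        src = rng.uniform(0, 10, size=(6, 3))
        t = np.array([2.5, -1.0, 4.0])
        field = tps_to_field(fit_tps(src, src + t, dim=3), self._grid())
        np.testing.assert_allclose(field.vectors - t, 0, atol=1e-7)

    def test_control_voxel_displacements_reproduced(self, rng):
        grid = self._grid()
        # control points exactly on voxel centres
        idx = np.array([[1, 1, 1], [4, 2, 3], [2, 5, 1], [3, 3, 2],
                        [1, 4, 3], [4, 5, 0]])
        src = grid.index_to_physical(idx)
        dst = src + rng.normal(size=src.shape)
        field = tps_to_field(fit_tps(src, dst, dim=3), grid)
        for n, (i, j, k) in enumerate(idx):
            np.testing.assert_allclose(field.vectors[i, j, k],
                                       dst[n] - src[n], atol=1e-6)


class TestWarp:
    def test_zero_field_reproduces_template(self, rng):
        img = VolumeImage(rng.normal(size=(8, 8, 8)))
        field = DisplacementField(np.zeros((8, 8, 8, 3)))
        np.testing.assert_allclose(warp_image(img, field).data, img.data,
                                   atol=1e-12)

    def test_integer_voxel_translation_is_exact_on_overlap(self, rng):
        img = VolumeImage(rng.normal(size=(10, 10, 10)), spacing=(2.0, 2.0, 2.0))
        field = DisplacementField(
            np.broadcast_to([4.0, 0.0, 0.0], (10, 10, 10, 3)).copy(),
            spacing=(2.0, 2.0, 2.0),
        )
        out = warp_image(img, field)
        np.testing.assert_allclose(out.data[:8], img.data[2:], atol=1e-12)

    def test_smooth_field_round_trip_is_small(self, small_phantom_3d):
        _, img, _ = small_phantom_3d
        rng = np.random.default_rng(5)
        base = rng.normal(size=(3, 3, 3, 3))
        from scipy.ndimage import zoom

        smooth = np.stack(
            [zoom(base[..., c], 16, order=3) for c in range(3)], axis=-1
        ) * 2.0
        field = DisplacementField(smooth, spacing=img.spacing)
        neg = DisplacementField(-smooth, spacing=img.spacing)
        round_trip = warp_image(warp_image(img, field), neg)
        span = img.data.max() - img.data.min()
        inner = (slice(8, -8),) * 3
        diff = np.abs(round_trip.data[inner] - img.data[inner]).mean()
        assert diff < 0.05 * span

    def test_dimensionality_mismatch_rejected(self, rng):
        img2d = VolumeImage(rng.normal(size=(8, 8, 1)))
        field3d = DisplacementField(np.zeros((8, 8, 8, 3)))
        with pytest.raises(ValueError, match="mismatch"):
            warp_image(img2d, field3d)
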