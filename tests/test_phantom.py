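"""Digital phantom generation and analytic deformation tests."""

import numpy as np
import pytest

from featwarp import (
    GaussianLobeDeformation,
    HarmonicDeformation,
    LandmarkSet,
    Marker,
    PhantomSpec,
    TranslationDeformation,
    body_mask,
    deform_phantom,
    generate_phantom,
    harmonic_displace,
    random_markers,
)


class TestHarmonic:
    def test_b_zero_is_identity(self, rng):
        d = HarmonicDeformation(b=0.0, m=5)
        pts = rng.uniform(-50, 50, size=(20, 3))
        np.testing.assert_allclose(d.forward(pts), pts)

    def test_m_zero_scales_x_only(self):
        d = HarmonicDeformation(b=0.1, m=0)
        np.testing.assert_allclose(
            harmonic_displace(np.array([10.0, 5.0]), d), [11.0, 5.0]
        )

    def test_y_axis_is_fixed(self):
        d = HarmonicDeformation(b=0.3, m=3)
        np.testing.assert_allclose(
            harmonic_displace(np.array([0.0, 7.0]), d), [0.0, 7.0]
        )

    def test_y_and_z_never_move(self, rng):
        d = HarmonicDeformation(b=0.2, m=4, center=(3.0, -2.0, 0.0))
        pts = rng.uniform(-40, 40, size=(30, 3))
        out = d.forward(pts)
        np.testing.assert_allclose(out[:, 1:], pts[:, 1:])

    @pytest.mark.parametrize("m", [0, 1, 2, 4, 7])
    def test_inverse_round_trip(self, rng, m):
        d = HarmonicDeformation(b=0.15, m=m, center=(5.0, 5.0, 0.0))
        pts = rng.uniform(-80, 90, size=(200, 3))
        np.testing.assert_allclose(d.inverse(d.forward(pts)), pts, atol=1e-6)

    def test_magnitude_bound_enforced(self):
        with pytest.raises(ValueError, match="orientation-preserving"):
            HarmonicDeformation(b=1.0, m=2)


class TestGaussianLobes:
    def test_forward_inverse_round_trip(self, rng):
        d = GaussianLobeDeformation.random(
            rng, np.array([50.0, 50.0, 50.0]), np.array([40.0, 40.0, 40.0]),
            peak=10.0, sigma=40.0,
        )
        pts = rng.uniform(0, 100, size=(100, 3))
        np.testing.assert_allclose(d.inverse(d.forward(pts)), pts, atol=1e-6)

    def test_peak_normalisation(self, rng):
        d = GaussianLobeDeformation.random(
            rng, np.zeros(3), np.array([50.0, 50.0, 50.0]), peak=18.0,
        )
        probe = rng.uniform(-50, 50, size=(5000, 3))
        mags = np.linalg.norm(d.displacement(probe), axis=1)
        # normalisation is sample-based; the true peak agrees to a few %
        assert mags.max() <= 18.0 * 1.05
        assert mags.max() > 12.0  # the peak lives inside the region

    def test_overly_strong_field_rejected_before_resampling(self, rng):
        img = VolumeImageFactory(rng)
        d = GaussianLobeDeformation(
            centers=np.array([[20.0, 20.0, 20.0]]),
            amplitudes=np.array([[60.0, 0.0, 0.0]]),
            sigma=10.0,
        )
        with pytest.raises(ValueError, match="not invertible"):
            deform_phantom(img, LandmarkSet(np.zeros((0, 3))), d)


def VolumeImageFactory(rng):
    from featwarp import VolumeImage

    return VolumeImage(rng.normal(size=(20, 20, 20)), spacing=(2.0, 2.0, 2.0))


class TestGeneratePhantom:
    def test_deterministic_under_fixed_seed(self, small_phantom_3d):
        spec, image, markers = small_phantom_3d
        again, markers2 = generate_phantom(spec)
        np.testing.assert_array_equal(again.data, image.data)
        np.testing.assert_array_equal(markers2.points, markers.points)

    def test_flat_phantom_is_piecewise_constant(self):
        spec = PhantomSpec(dims=(32, 32, 32), spacing=(2.0,) * 3,
                           body_semiaxes=(25.0, 25.0, 25.0),
                           boundary_amplitude=0.0, texture_blobs=0,
                           bone_features=0, smooth_sigma=0.0)
        image, _ = generate_phantom(spec)
        assert set(np.unique(image.data)) == {-1000.0, 40.0}

    def test_body_has_distinct_intensity_from_background(self, small_phantom_3d):
        spec, image, _ = small_phantom_3d
        mask = body_mask(spec)
        assert image.data[~mask].mean() < -800
        assert image.data[mask].mean() > -200

    def test_requested_markers_are_returned_inside_body(self):
        spec = PhantomSpec(dims=(64, 64, 64), spacing=(2.0,) * 3,
                           body_semiaxes=(55.0, 55.0, 55.0), seed=3)
        marks = random_markers(spec, 20, min_separation=12.0)
        spec = PhantomSpec(**{**spec.__dict__, "markers": marks})
        image, landmarks = generate_phantom(spec)
        assert len(landmarks) == 20
        mask = body_mask(spec)
        for p in landmarks.points:
            idx = tuple(np.round(image.physical_to_index(p)).astype(int))
            assert mask[idx]

    def test_marker_outside_body_rejected(self):
        spec = PhantomSpec(dims=(32, 32, 32), spacing=(2.0,) * 3,
                           body_semiaxes=(20.0, 20.0, 20.0),
                           markers=(Marker((60.0, 31.0, 31.0), 4.0, 500.0),))
        with pytest.raises(ValueError, match="marker"):
            generate_phantom(spec)


class TestDeformPhantom:
    def test_identity_deformation_changes_nothing(self, small_phantom_3d):
        _, image, markers = small_phantom_3d
        target, moved, truth = deform_phantom(
            image, markers, TranslationDeformation((0.0, 0.0, 0.0))
        )
        np.testing.assert_allclose(target.data, image.data, atol=1e-9)
        np.testing.assert_array_equal(moved.points, markers.points)
        assert np.all(truth.vectors == 0)

    def test_translation_moves_markers_exactly(self, small_phantom_3d):
        _, image, markers = small_phantom_3d
        t = (6.0, -4.0, 2.0)
        target, moved, truth = deform_phantom(
            image, markers, TranslationDeformation(t)
        )
        np.testing.assert_allclose(moved.points - markers.points,
                                   np.broadcast_to(t, markers.points.shape))
        np.testing.assert_allclose(truth.vectors[..., :],
                                   np.broadcast_to([-6.0, 4.0, -2.0],
                                                   truth.vectors.shape))

    def test_harmonic_marker_transport_is_analytic(self, small_phantom_2d):
        spec, image, _ = small_phantom_2d
        markers = LandmarkSet(np.array([[60.0, 50.0, 0.0], [70.0, 80.0, 0.0]]))
        d = HarmonicDeformation(b=0.1, m=2, center=tuple(spec.center()))
        _, moved, _ = deform_phantom(image, markers, d)
        for before, after in zip(markers.points, moved.points):
            np.testing.assert_allclose(after, harmonic_displace(before, d),
                                       atol=1e-9)

    def test_ground_truth_maps_displaced_markers_home(self, small_phantom_3d):
        _, image, _ = small_phantom_3d
        markers = LandmarkSet(np.array(
            [[47.0, 47.0, 47.0], [60.0, 50.0, 40.0], [35.0, 55.0, 50.0]]
        ))
        rng = np.random.default_rng(2)
        d = GaussianLobeDeformation.random(
            rng, np.array([47.0, 47.0, 47.0]), np.array([30.0, 32.0, 34.0]),
            peak=8.0, sigma=40.0,
        )
        _, moved, truth = deform_phantom(image, markers, d)
        recovered = moved.points + truth.sample(moved.points)
        err = np.linalg.norm(recovered - markers.points, axis=1)
        assert err.max() < 0.05

    def test_2d_truth_has_two_components(self, small_phantom_2d):
        spec, image, markers = small_phantom_2d
        d = HarmonicDeformation(b=0.05, m=1, center=tuple(spec.center()))
        _, _, truth = deform_phantom(image, markers, d)
        assert truth.ncomp == 2
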