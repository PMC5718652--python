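"""Control-point transform: solving, factorization, distortion round trips."""

import numpy as np
import pytest

import portalreg as pr
from portalreg.geometry import (
    ControlPointSet,
    DegenerateControlPointsError,
    OrientationError,
    PlanarTransform,
    PointPairList,
    correct_image,
    decompose_transform,
    forward_distort,
    invert_distort,
    recompose_transform,
    solve_linear_map,
    working_area,
)


class TestSolveLinearMap:
    @pytest.mark.parametrize(
        "plate, expected",
        [
            ([[100.0, 0.0], [0.0, 100.0]], np.eye(2)),  # identity
            ([[50.0, 0.0], [0.0, 50.0]], 0.5 * np.eye(2)),  # 2 mm/px plate
        ],
    )
    def test_axis_pairs(self, plate, expected):
        pairs = PointPairList([[100.0, 0.0], [0.0, 100.0]], plate)
        np.testing.assert_allclose(solve_linear_map(pairs), expected, atol=1e-12)

    def test_round_trip_recovers_known_matrix(self):
        M = recompose_transform(1.0, 7.0, 0.0, 10.0)
        beam = np.array([[100.0, 0.0], [0.0, 100.0]])
        pairs = PointPairList(beam, beam @ M.T)
        np.testing.assert_allclose(solve_linear_map(pairs), M, atol=1e-12)

    def test_exact_interpolation_of_input_pairs(self):
        rng = np.random.default_rng(3)
        beam = rng.uniform(-100, 100, (2, 2))
        plate = rng.uniform(-100, 100, (2, 2))
        M = solve_linear_map(PointPairList(beam, plate))
        np.testing.assert_allclose(beam @ M.T, plate, atol=1e-9)

    def test_singular_plate_vectors_raise(self):
        with pytest.raises(DegenerateControlPointsError, match=r"plate"):
            solve_linear_map(
                PointPairList([[100.0, 0.0], [0.0, 100.0]], [[50.0, 0.0], [100.0, 0.0]])
            )

    def test_dependent_beam_vectors_raise(self):
        with pytest.raises(DegenerateControlPointsError):
            PointPairList([[100.0, 0.0], [200.0, 0.0]], [[50.0, 0.0], [0.0, 50.0]])


class TestDecompose:
    def test_pure_zoom_rotation(self):
        b, th, ph, ti = decompose_transform(2.0 * np.array(
            [[np.cos(np.deg2rad(30)), -np.sin(np.deg2rad(30))],
             [np.sin(np.deg2rad(30)), np.cos(np.deg2rad(30))]]
        ))
        assert b == pytest.approx(2.0)
        assert th == pytest.approx(30.0)
        assert (ph, ti) == (0.0, 0.0)

    def test_pure_stretch(self):
        # diag(1,2): unit zoom, no rotation, stretch factor 2 = 1/cos(60°)
        b, th, ph, ti = decompose_transform(np.diag([1.0, 2.0]))
        assert b == pytest.approx(1.0)
        assert th == pytest.approx(0.0, abs=1e-12)
        assert ti == pytest.approx(60.0)
        M = recompose_transform(b, th, ph, ti)
        np.testing.assert_allclose(M, np.diag([1.0, 2.0]), atol=1e-9)

    def test_recomposition_property_1000_draws(self):
        rng = np.random.default_rng(42)
        n = 0
        while n < 1000:
            M = rng.uniform(-2, 2, (2, 2))
            if np.linalg.det(M) <= 1e-3:
                continue
            n += 1
            params = decompose_transform(M)
            err = np.abs(recompose_transform(*params) - M).max() / np.abs(M).max()
            assert err < 1e-9
            assert 0.0 <= params[3] < 90.0
            assert params[0] == pytest.approx(np.linalg.svd(M, compute_uv=False)[1])

    def test_orientation_reversing_rejected(self):
        with pytest.raises(OrientationError):
            decompose_transform(np.diag([1.0, -1.0]))


class TestForwardDistort:
    def _pt(self, M):
        return PlanarTransform(linear=M, translation=[0.0, 0.0])

    def test_identity(self):
        t = self._pt(np.eye(2))
        np.testing.assert_allclose(forward_distort([13.0, -7.0], t), [13.0, -7.0])

    def test_tilt_stretches_perpendicular_axis(self):
        t = self._pt(recompose_transform(1.0, 0.0, 0.0, 10.0))
        out = forward_distort([0.0, 100.0], t)
        np.testing.assert_allclose(out, [0.0, 100.0 / np.cos(np.deg2rad(10.0))], atol=1e-9)
        assert out[1] == pytest.approx(101.5427, abs=1e-3)

    def test_tilt_axis_direction_unstretched(self):
        t = self._pt(recompose_transform(1.0, 0.0, 0.0, 10.0))
        np.testing.assert_allclose(forward_distort([100.0, 0.0], t), [100.0, 0.0], atol=1e-9)

    def test_point_round_trip(self):
        t = PlanarTransform(recompose_transform(1.2, 5.0, 30.0, 20.0), [3.0, -4.0])
        rng = np.random.default_rng(0)
        pts = rng.uniform(-100, 100, (50, 2))
        np.testing.assert_allclose(invert_distort(forward_distort(pts, t), t), pts, atol=1e-9)


class TestCorrectImage:
    def test_identity_transform_preserves_image(self, smooth_image):
        t = PlanarTransform(np.eye(2), smooth_image.frame.isocenter_px * np.array([1.0, -1.0]))
        out = correct_image(smooth_image, t, smooth_image.frame)
        np.testing.assert_allclose(out.intensities, smooth_image.intensities, atol=1e-9)

    def test_distort_then_correct_round_trip(self, smooth_image):
        frame = smooth_image.frame
        iso_math = np.array([frame.isocenter_px[0], -frame.isocenter_px[1]])
        M = recompose_transform(1.0, 4.0, 0.0, 10.0)
        t = PlanarTransform(M, iso_math)
        # build the distorted plate image by sampling through the forward map
        distorted = correct_image(smooth_image, PlanarTransform(np.linalg.inv(M), iso_math), frame)
        corrected = correct_image(distorted, t, frame)
        inner = np.s_[20:-20, 20:-20]
        rng_i = smooth_image.intensities.max() - smooth_image.intensities.min()
        rms = np.sqrt(
            np.mean((corrected.intensities[inner] - smooth_image.intensities[inner]) ** 2)
        )
        assert rms / rng_i < 0.01

    def test_scaling_coordinate_bookkeeping(self, smooth_image):
        # 2 mm/px plate: a feature 50 px from the plate isocenter is 100 mm out
        frame = smooth_image.frame
        iso_math = np.array([frame.isocenter_px[0], -frame.isocenter_px[1]])
        t = PlanarTransform(0.5 * np.eye(2), iso_math)
        plate = np.zeros(smooth_image.shape)
        col = int(frame.isocenter_px[0]) + 50
        plate[int(frame.isocenter_px[1]), col] = 1000.0
        plate_img = pr.ImageGrid(plate, (2.0, 2.0))
        out = correct_image(plate_img, t, pr.BeamFrame(frame.isocenter_px, 2.0))
        r, c = np.unravel_index(np.argmax(out.intensities), out.shape)
        x_mm, y_mm = pr.BeamFrame(frame.isocenter_px, 2.0).px_to_mm([c, r])
        assert (x_mm, y_mm) == pytest.approx((100.0, 0.0), abs=1.0)

    def test_out_of_footprint_flagged_background(self, smooth_image):
        t = PlanarTransform(np.eye(2), [500.0, 0.0])  # shifted far off the plate
        out = correct_image(smooth_image, t, smooth_image.frame)
        assert not out.background_mask.all()
        assert out.intensities[~out.background_mask].max(initial=0.0) == 0.0


class TestControlPoints:
    def test_collinear_points_rejected(self):
        with pytest.raises(DegenerateControlPointsError, match="collinear"):
            ControlPointSet((0, 0), (10, 0), (20, 0))

    def test_beam_frame_spacing_calibration(self):
        cps = ControlPointSet((100, 100), (150, 100), (100, 50), axis_length_mm=100.0)
        assert cps.beam_frame().pixel_spacing_mm == pytest.approx(2.0)

    @pytest.mark.parametrize(
        "point, expected",
        [((50.0, 50.0), True), ((150.0, 150.0), False), ((100.0, 0.0), True)],
    )
    def test_working_area_box(self, point, expected):
        cps = ControlPointSet((0, 0), (100, 0), (0, -100), axis_length_mm=100.0)
        assert working_area(cps, point) is expected


class TestTransformFromControlPoints:
    def test_known_scaling_and_translation(self):
        # portal at 2 mm/px: axis points 50 px out; isocenter off-center
        cps_drr = ControlPointSet((64, 64), (164, 64), (64, -36), axis_length_mm=100.0)
        cps_portal = ControlPointSet((80, 70), (130, 70), (80, 20), axis_length_mm=100.0)
        t = pr.transform_from_control_points(cps_drr, cps_portal)
        np.testing.assert_allclose(t.linear, 0.5 * np.eye(2), atol=1e-12)
        np.testing.assert_allclose(t.translation, [80.0, -70.0])
        assert t.zoom_b == pytest.approx(0.5)
        assert t.tilt_deg == 0.0
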