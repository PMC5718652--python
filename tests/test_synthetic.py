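"""Synthetic phantom generator: determinism, scene structure, tilt geometry."""

import numpy as np
import pytest

import portalreg as pr
from portalreg import synthetic as syn
from .conftest import SMALL, make_portal


class TestScenes:
    def test_same_seed_identical_scene(self):
        a = syn.make_scene("chest", seed=3)
        b = syn.make_scene("chest", seed=3)
        assert a == b
        drr_a = syn.render_drr(a, **SMALL)
        drr_b = syn.render_drr(b, **SMALL)
        np.testing.assert_array_equal(drr_a.intensities, drr_b.intensities)

    def test_chest_has_stronger_gradients_than_pelvis(self):
        ga, gp = [], []
        for seed in range(3):
            for kind, acc in (("chest", ga), ("pelvis", gp)):
                img = syn.render_drr(syn.make_scene(kind, seed=seed), **SMALL).intensities
                gy, gx = np.gradient(img)
                acc.append(np.mean(np.hypot(gx, gy)))
        assert np.mean(ga) > np.mean(gp)

    def test_structures_within_extent(self):
        for kind in ("chest", "pelvis"):
            scene = syn.make_scene(kind, seed=0)
            for s in scene.structures:
                assert abs(s.cx) <= scene.extent_mm and abs(s.cy) <= scene.extent_mm

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            syn.make_scene("cranium", seed=0)


class TestRenderDrr:
    def test_ticks_at_centimeter_marks(self, small_drr):
        frame = small_drr.frame
        for k in range(-5, 6):
            col, row = frame.mm_to_px([k * 10.0, 0.0])
            assert small_drr.intensities[int(round(row)), int(round(col))] == syn._TICK_VALUE

    def test_field_border_at_pm_50mm(self, small_drr):
        frame = small_drr.frame
        for corner in [(50.0, 50.0), (-50.0, 50.0), (50.0, -50.0), (-50.0, -50.0)]:
            col, row = frame.mm_to_px(list(corner))
            assert small_drr.intensities[int(round(row)), int(round(col))] == syn._TICK_VALUE

    def test_isocenter_marked(self, small_drr):
        col, row = small_drr.frame.mm_to_px([0.0, 0.0])
        assert small_drr.intensities[int(round(row)), int(round(col))] == syn._TICK_VALUE


class TestRenderPortal:
    def test_zero_offset_clean_portal_aligns_with_drr(self, chest_scene, small_drr):
        portal = make_portal(chest_scene, (0.0, 0.0), contrast=1.0, noise_sigma=0.0)
        # anatomy identical away from graticule: compare off-axis quadrant interiors
        region = np.s_[16:48, 16:48]
        d = small_drr.intensities[region]
        p = portal.intensities[region]
        np.testing.assert_allclose(p, d, atol=1e-9)

    def test_offset_moves_anatomy_correlation_peak(self, chest_scene):
        a = make_portal(chest_scene, (0.0, 0.0), noise_sigma=0.0).intensities
        b = make_portal(chest_scene, (5.0, 0.0), noise_sigma=0.0).intensities
        # correlate an interior anatomy window (clear of the offset-invariant
        # burned-in graticule) against laterally shifted windows of the
        # offset portal: the correlation peak sits at the true +5 px shift
        win = np.s_[20:58, 72:104]  # x in [8.5, 40.5] mm, y in [5.5, 43.5] mm
        wa = a[win] - a[win].mean()

        def score(k):
            wb = b[20:58, 72 + k : 104 + k]
            wb = wb - wb.mean()
            return float((wa * wb).sum() / np.sqrt((wa**2).sum() * (wb**2).sum()))

        shifts = range(-8, 9)
        best = max(shifts, key=score)
        assert best == 5

    def test_graticule_stays_at_nominal_position(self, chest_scene):
        portal = make_portal(chest_scene, (7.0, -4.0), noise_sigma=0.0)
        frame = portal.frame
        col, row = frame.mm_to_px([50.0, 50.0])  # field corner, unshifted
        assert portal.intensities[int(round(row)), int(round(col))] == syn._TICK_VALUE

    def test_contrast_compresses_histogram(self, chest_scene):
        full = make_portal(chest_scene, (0.0, 0.0), contrast=1.0, noise_sigma=0.0)
        low = make_portal(chest_scene, (0.0, 0.0), contrast=0.2, noise_sigma=0.0)
        region = np.s_[16:48, 16:48]  # anatomy only, no graticule
        w_full = np.percentile(full.intensities[region], 99) - np.percentile(
            full.intensities[region], 1
        )
        w_low = np.percentile(low.intensities[region], 99) - np.percentile(
            low.intensities[region], 1
        )
        assert w_full / w_low == pytest.approx(5.0, rel=0.1)

    def test_noise_seeded_deterministic(self, chest_scene):
        a = make_portal(chest_scene, (1.0, 1.0), noise_sigma=8.0, seed=11)
        b = make_portal(chest_scene, (1.0, 1.0), noise_sigma=8.0, seed=11)
        np.testing.assert_array_equal(a.intensities, b.intensities)


class TestCaseList:
    def test_five_offsets_give_ten_cases(self):
        cl = syn.make_case_list("chest", seed=0)
        assert len(cl.cases) == 10
        ids = [c.case_id for c in cl.cases]
        assert all(ids.count(i) == 2 for i in set(ids))

    def test_offsets_within_ten_mm(self):
        cl = syn.make_case_list("chest", seed=1)
        for c in cl.cases:
            assert abs(c.true_offset[0]) <= 10.0 and abs(c.true_offset[1]) <= 10.0

    def test_repeats_share_offset_and_have_both_indices(self):
        cl = syn.make_case_list("pelvis", seed=2)
        by_id = {}
        for c in cl.cases:
            by_id.setdefault(c.case_id, []).append(c)
        for pair in by_id.values():
            assert sorted(p.repeat_index for p in pair) == [1, 2]
            assert pair[0].true_offset == pair[1].true_offset

    def test_shuffle_permutes_same_multiset(self):
        a = syn.make_case_list("chest", seed=5)
        b = syn.CaseList(
            cases=tuple(sorted(a.cases, key=lambda c: (c.case_id, c.repeat_index))),
            shuffle_seed=0,
        )
        assert sorted(map(repr, a.cases)) == sorted(map(repr, b.cases))


class TestTiltedPlate:
    def test_zero_tilt_is_pure_magnification(self):
        pts = np.array([[30.0, -40.0], [0.0, 100.0]])
        out = syn.project_beam_points(pts, tilt_deg=0.0, source_mm=1000.0, plate_mm=400.0)
        np.testing.assert_allclose(out, pts * 1.4, atol=1e-9)

    def test_foreshortening_perpendicular_to_tilt_axis(self):
        # plate tilted about the x axis: y distances shrink on the plate
        # relative to the zero-tilt magnification, x distances do not
        o = syn.project_beam_points(np.array([0.0, 0.0]), 10.0)
        px = syn.project_beam_points(np.array([100.0, 0.0]), 10.0)
        py = syn.project_beam_points(np.array([0.0, 100.0]), 10.0)
        flat = 1.4 * 100.0
        assert abs(px[0] - o[0]) == pytest.approx(flat, rel=1e-9)
        assert abs(py[1] - o[1]) < flat

    def test_residual_ordering_inside_vs_outside(self):
        inside, outside = syn.tilt_experiment_residuals(tilt_deg=10.0)
        assert 0 < inside < outside

    def test_excessive_tilt_rejected(self):
        with pytest.raises(ValueError, match="45"):
            syn.project_beam_points(np.array([0.0, 0.0]), tilt_deg=60.0)

    def test_control_points_land_where_projected(self, small_drr):
        plate, cps = syn.simulate_tilted_plate(small_drr, 10.0, 0.0, 1000.0, 400.0)
        assert plate.frame is None
        # correcting with the returned control points must restore the graticule:
        # solve the transform and round-trip the isocenter
        cset = pr.ControlPointSet(
            cps["isocenter"], cps["axis_point_x"], cps["axis_point_y"], axis_length_mm=100.0
        )
        drr_cset = pr.ControlPointSet(
            small_drr.frame.isocenter_px,
            tuple(small_drr.frame.mm_to_px([100.0, 0.0])),
            tuple(small_drr.frame.mm_to_px([0.0, 100.0])),
        )
        t = pr.transform_from_control_points(drr_cset, cset)
        iso_plate = pr.forward_distort([0.0, 0.0], t)
        np.testing.assert_allclose(
            iso_plate, [cps["isocenter"][0], -cps["isocenter"][1]], atol=1e-9
        )


class TestCaseValidation:
    def test_offset_beyond_ten_mm_rejected(self):
        with pytest.raises(ValueError, match="10 mm"):
            syn.SyntheticCase("x", (12.0, 0.0))

    def test_contrast_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="contrast"):
            syn.SyntheticCase("x", (0.0, 0.0), contrast=0.0)
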