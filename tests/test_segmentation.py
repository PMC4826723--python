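"""Tests for contour handling, propagation, masks, centerline and layers."""

import numpy as np
import pytest

import tpmtorsion as tt
from tpmtorsion.phantom import analytic_contours
from tpmtorsion.segmentation import (
    ContourError,
    circle_contour,
    resample_closed_contour,
)

from conftest import rigid_rotation_series


def zero_velocity_series(n_frames=6, shape=(64, 64)):
    return tt.TPMSeries(
        slice_label="mid",
        magnitude=np.ones((n_frames, *shape)),
        velocity=np.zeros((3, n_frames, *shape)),
        pixel_spacing=(2.0, 2.0), dt_ms=20.0, slice_position_mm=0.0, venc_mm_s=250.0,
    )


class TestContourPair:
    def test_endo_outside_epi_rejected(self):
        pair = tt.ContourPair(
            epi=circle_contour((32, 32), 10), endo=circle_contour((32, 32), 15)
        )
        with pytest.raises(ContourError, match="inside"):
            pair.validate()

    def test_contour_json_round_trip(self, tmp_path):
        from tpmtorsion.segmentation import load_contours, save_contours

        pair = tt.ContourPair(
            epi=circle_contour((32, 32), 20), endo=circle_contour((32, 32), 10),
            frame_index=4,
        )
        save_contours(pair, tmp_path / "c.json")
        back = load_contours(tmp_path / "c.json")
        np.testing.assert_allclose(back.epi, pair.epi)
        assert back.frame_index == 4

    def test_resampling_preserves_circle(self):
        c = circle_contour((0, 0), 20, n=100)
        r = resample_closed_contour(c, 100)
        np.testing.assert_allclose(np.hypot(r[:, 0], r[:, 1]), 20, atol=0.05)


class TestRasterize:
    def test_annulus_area_matches_analytic(self):
        pair = tt.ContourPair(
            epi=circle_contour((64, 64), 25), endo=circle_contour((64, 64), 15)
        )
        mask = tt.rasterize_and_close(pair, (128, 128))
        expected = np.pi * (25**2 - 15**2)
        assert mask.sum() == pytest.approx(expected, rel=0.02)

    def test_cavity_survives_closing_when_contours_touch(self):
        # one endo vertex pushed out until it touches the epicardium: closing
        # bridges the resulting cut without filling the cavity
        epi = circle_contour((64, 64), 15)
        endo = circle_contour((64, 64), 10)
        endo[0] = [64.0, 79.0]
        mask = tt.rasterize_and_close(tt.ContourPair(epi=epi, endo=endo), (128, 128))
        from skimage.measure import label

        from tpmtorsion.segmentation import _count_holes

        assert _count_holes(mask) == 1
        assert label(mask, connectivity=2).max() == 1

    def test_degenerate_contour_is_an_error(self):
        bad = np.array([[10.0, 10.0], [10.0, 10.0], [10.0, 10.0]])
        with pytest.raises(ContourError):
            tt.rasterize_and_close(
                tt.ContourPair(epi=circle_contour((20, 20), 10), endo=bad), (40, 40)
            )


class TestCenterline:
    def annulus(self, r_i=15, r_o=25, shape=(128, 128), center=(64, 64)):
        rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
        r = np.hypot(rr - center[0], cc - center[1])
        return (r >= r_i) & (r <= r_o)

    def test_skeleton_lies_near_mid_radius(self):
        mask = self.annulus()
        skel = tt.extract_centerline(mask)
        rr, cc = np.nonzero(skel)
        radii = np.hypot(rr - 64, cc - 64)
        assert abs(radii.mean() - 20) < 1.0

    def test_thin_ring_returned_unchanged(self):
        ring = self.annulus(r_i=20, r_o=20.9)
        skel = tt.extract_centerline(ring)
        assert skel.sum() >= 0.9 * ring.sum()

    def test_disk_without_hole_rejected(self):
        rr, cc = np.mgrid[0:64, 0:64]
        disk = np.hypot(rr - 32, cc - 32) <= 15
        with pytest.raises(ValueError, match="holes"):
            tt.extract_centerline(disk)

    def test_fragmented_mask_rejected(self):
        mask = self.annulus()
        mask[:, 60:68] = False  # cut the ring into two arcs
        with pytest.raises(ValueError, match="components"):
            tt.extract_centerline(mask)


class TestLayers:
    def test_radial_split_and_partition(self):
        pair = tt.ContourPair(
            epi=circle_contour((64, 64), 25), endo=circle_contour((64, 64), 15)
        )
        mask = tt.rasterize_and_close(pair, (128, 128))
        center = tt.extract_centerline(mask)
        layers = tt.label_layers(mask, center, pair)
        # pixel at radius 17 endocardial, at 23 epicardial
        assert layers[64, 64 + 17] == 1
        assert layers[64, 64 + 23] == 2
        # partition: every mask pixel gets exactly one label, nothing outside
        assert ((layers > 0) == mask).all()
        # outer band spans the larger circumference
        assert (layers == 1).sum() < (layers == 2).sum()

    def test_open_centerline_is_an_error(self):
        mask = np.zeros((32, 32), bool)
        mask[10:20, 10:20] = True
        open_line = np.zeros_like(mask)
        open_line[15, 10:18] = True
        with pytest.raises(ValueError, match="closed loop"):
            tt.label_layers(mask, open_line, None)


class TestPropagation:
    def test_zero_velocity_keeps_contours_fixed(self):
        s = zero_velocity_series()
        start = tt.ContourPair(
            epi=circle_contour((32, 32), 14), endo=circle_contour((32, 32), 8),
            frame_index=2,
        )
        frames = tt.propagate_contours(start, s)
        for cp in frames:
            np.testing.assert_allclose(cp.epi, frames[2].epi, atol=1e-12)

    def test_rigid_rotation_matches_analytic_within_005px(self):
        # 30 deg/s for 1 s: vertex at 20 px radius lands on its rotated image
        s = rigid_rotation_series(omega_deg_s=30.0, n_frames=51, dt_ms=20.0)
        center = np.array([47.5, 47.5])
        start = tt.ContourPair(
            epi=circle_contour(tuple(center), 20), endo=circle_contour(tuple(center), 10),
            frame_index=0,
        )
        frames = tt.propagate_contours(start, s)
        phi = np.deg2rad(30.0 * 1.0)
        rot = np.array([[np.cos(phi), np.sin(phi)], [-np.sin(phi), np.cos(phi)]])
        expected = (start.epi - center) @ rot.T + center
        err = np.linalg.norm(frames[50].epi - expected, axis=1)
        assert err.max() < 0.05

    def test_uniform_translation_shifts_one_pixel(self):
        s = zero_velocity_series(n_frames=21)
        s.velocity[0] = 5.0  # mm/s along columns; 2 mm pixels; 0.4 s -> +1 px
        start = tt.ContourPair(
            epi=circle_contour((32, 32), 14), endo=circle_contour((32, 32), 8),
            frame_index=0,
        )
        frames = tt.propagate_contours(start, s)
        shift = frames[20].epi - start.resampled().epi
        np.testing.assert_allclose(shift[:, 1], 1.0, atol=1e-9)
        np.testing.assert_allclose(shift[:, 0], 0.0, atol=1e-9)

    def test_cycle_consistency_on_periodic_phantom(self, clean_phantom):
        spec, slices, _ = clean_phantom
        s = slices.series["base"]
        start = analytic_contours(spec, "base", frame_index=0)
        frames = tt.propagate_contours(start, s)
        from tpmtorsion.segmentation import _advect_contour, _velocity_px_per_frame

        flow = _velocity_px_per_frame(s)
        final = _advect_contour(
            frames[-1].epi, flow, float(s.n_frames - 1), 1.0, s.shape, rk_order=4
        )
        err = np.linalg.norm(final - frames[0].epi, axis=1)
        assert err.max() < 0.5


class TestSnakeRefinement:
    def test_zero_force_shrinks_area_under_five_percent(self):
        s = zero_velocity_series()
        start = tt.ContourPair(
            epi=circle_contour((32, 32), 20), endo=circle_contour((32, 32), 10),
        )
        refined = tt.refine_contours(start, s)
        from tpmtorsion.segmentation import _shoelace_area

        a0 = _shoelace_area(start.resampled().epi)
        a1 = _shoelace_area(refined.epi)
        assert a1 > 0.95 * a0

    def test_converges_onto_annulus_velocity_edge(self):
        # velocity nonzero only inside an annulus; a circle started 2 px
        # outside must settle on the outer velocity edge
        s = zero_velocity_series(n_frames=3, shape=(96, 96))
        rr, cc = np.mgrid[0:96, 0:96]
        r = np.hypot(rr - 48, cc - 48)
        annulus = (r >= 10) & (r <= 18)
        s.velocity[0, :, annulus] = 20.0
        start = tt.ContourPair(
            epi=circle_contour((48, 48), 20), endo=circle_contour((48, 48), 6),
            frame_index=0,
        )
        refined = tt.refine_contours(start, s)
        radii = np.hypot(refined.epi[:, 0] - 48, refined.epi[:, 1] - 48)
        assert np.abs(radii - 18).mean() < 1.0

    def test_crossed_initial_contours_rejected(self):
        s = zero_velocity_series()
        start = tt.ContourPair(
            epi=circle_contour((32, 32), 8), endo=circle_contour((32, 32), 14),
        )
        with pytest.raises(ContourError):
            tt.refine_contours(start, s)


class TestSegmentSeries:
    def test_mask_area_varies_smoothly(self, clean_phantom):
        spec, slices, _ = clean_phantom
        s = slices.series["mid"]
        seg = tt.segment_series(s, analytic_contours(spec, "mid", 0))
        areas = seg.mask.sum(axis=(1, 2)).astype(float)
        rel_change = np.abs(np.diff(areas)) / areas[:-1]
        assert rel_change.max() < 0.25

    def test_layer_partition_every_frame(self, clean_phantom):
        spec, slices, _ = clean_phantom
        s = slices.series["mid"]
        seg = tt.segment_series(s, analytic_contours(spec, "mid", 0))
        for t in range(seg.n_frames):
            endo = seg.layer_mask("endo", t)
            epi = seg.layer_mask("epi", t)
            assert not (endo & epi).any()
            assert ((endo | epi) == seg.mask[t]).all()
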