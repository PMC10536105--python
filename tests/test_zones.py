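"""ROI detection, symmetry point, zone masks and illuminance."""

import numpy as np
import pytest

from erphot.synth import OcclusionSpec
from erphot.zones import (
    RegionOfInterest,
    RoiNotFoundError,
    SymmetryPoint,
    ZoneGeometry,
    average_replicates,
    detect_roi,
    illuminance_table,
    symmetry_point,
    zone_illuminance,
    zone_masks,
)
from conftest import make_frame


def disk_frame(shape, center, radius, level=200.0, background=0.0):
    rows = np.arange(shape[0])[:, None] + 0.5
    cols = np.arange(shape[1])[None, :] + 0.5
    dist = np.hypot(rows - center[0], cols - center[1])
    pixels = np.where(dist < radius, level, background)
    return make_frame(pixels)


def brute_bbox(pixels, threshold):
    """Oracle: half-open bounding box of pixels >= threshold, by full scan."""
    hits = [
        (r, c)
        for r in range(pixels.shape[0])
        for c in range(pixels.shape[1])
        if pixels[r, c] >= threshold
    ]
    rows = [h[0] for h in hits]
    cols = [h[1] for h in hits]
    return min(rows), min(cols), max(rows) + 1, max(cols) + 1


class TestDetectRoi:
    def test_matches_brute_force_bounding_box_of_disk(self):
        frame = disk_frame((220, 220), (100.0, 100.0), 20.0)
        roi = detect_roi(frame, tau0=0.5)
        r0, c0, r1, c1 = brute_bbox(frame.pixels, 0.5 * frame.pixels.max())
        assert (roi.row0, roi.col0, roi.row1, roi.col1) == (r0, c0, r1, c1)
        assert roi.form_value == 1.0
        assert roi.threshold_used == 0.5

    def test_all_zero_frame_raises(self):
        with pytest.raises(RoiNotFoundError, match="no bright area"):
            detect_roi(make_frame(np.zeros((32, 32))))

    def test_elongated_bar_fails_reporting_form_value(self):
        pixels = np.zeros((100, 100))
        pixels[45:55, 30:70] = 255.0  # 10 x 40 bar
        with pytest.raises(RoiNotFoundError) as err:
            detect_roi(make_frame(pixels), form_limits=(0.8, 1.25))
        assert err.value.form_value == pytest.approx(0.25)

    def test_threshold_lowered_until_form_acceptable(self):
        # bright bar plus a dimmer square halo: only a lower threshold
        # produces a square bright area
        pixels = np.zeros((100, 100))
        pixels[30:70, 30:70] = 100.0
        pixels[48:52, 30:70] = 255.0
        roi = detect_roi(make_frame(pixels), tau0=0.5, tau_step=0.05)
        assert roi.threshold_used < 0.5
        assert 0.8 <= roi.form_value <= 1.25
        assert (roi.row0, roi.col0, roi.row1, roi.col1) == (30, 30, 70, 70)


class TestSymmetryPoint:
    @pytest.mark.parametrize(
        "bounds, rc, parity",
        [
            ((0, 0, 5, 5), (2.5, 2.5), "odd"),  # side 5: central pixel (2,2)
            ((0, 0, 4, 4), (2.0, 2.0), "even"),  # side 4: corner of 4 central px
            ((80, 80, 122, 122), (101.0, 101.0), "even"),  # side 42
        ],
    )
    def test_center_is_midpoint_of_half_open_bounds(self, bounds, rc, parity):
        roi = RegionOfInterest(*bounds, threshold_used=0.5, form_value=1.0)
        sp = symmetry_point(roi)
        assert sp.rc == rc
        assert sp.parity == parity


def geometry(rc, radii=(5.0, 10.0, 20.0)):
    return ZoneGeometry(
        center=SymmetryPoint(rc=rc, parity="even"),
        R1_px=radii[0], R2_px=radii[1], R3_px=radii[2],
    )


def brute_force_masks(geom, shape):
    a1 = np.zeros(shape, dtype=bool)
    a2 = np.zeros(shape, dtype=bool)
    a3 = np.zeros(shape, dtype=bool)
    for r in range(shape[0]):
        for c in range(shape[1]):
            dist = np.hypot(r + 0.5 - geom.center.rc[0], c + 0.5 - geom.center.rc[1])
            if dist < geom.R1_px:
                a1[r, c] = True
            elif dist < geom.R2_px:
                a2[r, c] = True
            elif dist < geom.R3_px:
                a3[r, c] = True
    return a1, a2, a3


class TestZoneMasks:
    def test_unit_radius_at_pixel_center_selects_one_pixel(self):
        geom = geometry((10.5, 10.5), (1.0, 2.0, 5.0))
        a1, _, _ = zone_masks(geom, (21, 21))
        assert a1.sum() == 1
        assert a1[10, 10]

    def test_partition_of_outer_disk(self):
        geom = geometry((24.0, 24.0))
        a1, a2, a3 = zone_masks(geom, (48, 48))
        assert not (a1 & a2).any() and not (a2 & a3).any() and not (a1 & a3).any()
        rows = np.arange(48)[:, None] + 0.5
        cols = np.arange(48)[None, :] + 0.5
        disk = np.hypot(rows - 24.0, cols - 24.0) < geom.R3_px
        np.testing.assert_array_equal(a1 | a2 | a3, disk)

    def test_matches_brute_force_on_shifted_centers(self, rng):
        for _ in range(5):
            rc = tuple(rng.uniform(20, 28, size=2))
            geom = geometry(rc, (3.0, 8.0, 15.0))
            fast = zone_masks(geom, (48, 48))
            slow = brute_force_masks(geom, (48, 48))
            for f, s in zip(fast, slow):
                np.testing.assert_array_equal(f, s)

    def test_ring_area_near_continuum_value(self):
        geom = geometry((240.5, 320.5), (10.0, 20.0, 40.0))
        _, a2, _ = zone_masks(geom, (480, 640))
        # annulus 10 <= r < 20 has continuum area pi * 300
        assert a2.sum() == pytest.approx(np.pi * 300, rel=0.02)

    def test_outer_circle_must_fit(self):
        with pytest.raises(ValueError, match="exceeds"):
            zone_masks(geometry((10.0, 10.0)), (48, 48))


class TestZoneIlluminance:
    def test_uniform_frame_gives_uniform_illuminance(self):
        frame = make_frame(np.full((48, 48), 37.0))
        zi = zone_illuminance(frame, geometry((24.0, 24.0)))
        assert zi.E_A1 == zi.E_A2 == zi.E_A3 == 37.0

    def test_single_bright_pixel_scaled_by_ring_area(self):
        geom = geometry((24.0, 24.0))
        _, a2, _ = zone_masks(geom, (48, 48))
        pixels = np.zeros((48, 48))
        r, c = np.argwhere(a2)[0]
        pixels[r, c] = 200.0
        zi = zone_illuminance(make_frame(pixels), geom)
        assert zi.E_A2 == pytest.approx(200.0 / a2.sum())
        assert zi.E_A1 == 0.0

    def test_zone_sums_partition_disk_total(self, rng):
        geom = geometry((24.0, 24.0))
        pixels = rng.integers(0, 255, size=(48, 48)).astype(float)
        zi = zone_illuminance(make_frame(pixels), geom)
        a1, a2, a3 = zone_masks(geom, (48, 48))
        disk_sum = pixels[a1 | a2 | a3].sum()
        total = zi.E_A1 * zi.area_A1 + zi.E_A2 * zi.area_A2 + zi.E_A3 * zi.area_A3
        assert total == pytest.approx(disk_sum)
        assert zi.area_A1 + zi.area_A2 == int((a1 | a2).sum())

    def test_excluded_pixels_do_not_affect_result(self, rng):
        geom = geometry((24.0, 24.0))
        pixels = rng.integers(50, 150, size=(48, 48)).astype(float)
        occ = OcclusionSpec(rectangles=[(20, 20, 28, 28)], attenuation=0.0)
        base = zone_illuminance(make_frame(pixels), geom, exclude=occ)
        corrupted = pixels.copy()
        corrupted[20:28, 20:28] = 255.0  # arbitrary values under the exclusion
        after = zone_illuminance(make_frame(corrupted), geom, exclude=occ)
        assert after.E_A1 == base.E_A1
        assert after.E_A2 == base.E_A2
        assert after.E_A3 == base.E_A3

    def test_fully_excluded_zone_raises(self):
        geom = geometry((24.0, 24.0), (2.0, 20.0, 23.0))
        occ = OcclusionSpec(rectangles=[(20, 20, 28, 28)], attenuation=0.0)
        with pytest.raises(ValueError, match="A1"):
            zone_illuminance(make_frame(np.ones((48, 48))), geom, exclude=occ)


class TestAverageReplicates:
    def _zi(self, E, site, capture, thickness=2.0, power=4.2, mode="transmitted"):
        from erphot.zones import ZoneIlluminance

        return ZoneIlluminance(
            E_A1=E, E_A2=E, E_A3=E, area_A1=10, area_A2=20, area_A3=30,
            thickness_mm=thickness, power_mW=power, mode=mode,
            site_index=site, capture_index=capture,
        )

    def test_mean_of_simple_values(self):
        ms = [self._zi(E, 1, i + 1) for i, E in enumerate((1.0, 2.0, 3.0))]
        out = average_replicates(ms)
        assert len(out) == 1
        assert out.loc[0, "E_A2"] == pytest.approx(2.0)
        assert out.loc[0, "n_replicates"] == 3

    def test_identical_measurements_pass_through(self):
        ms = [self._zi(7.5, s, c) for s in (1, 2) for c in (1, 2)]
        out = average_replicates(ms)
        assert out.loc[0, "E_A3"] == 7.5

    def test_nine_replicates_equal_brute_force_mean(self, rng):
        values = rng.normal(100, 5, size=9)
        ms = [
            self._zi(v, s + 1, c + 1)
            for v, (s, c) in zip(values, [(s, c) for s in range(3) for c in range(3)])
        ]
        out = average_replicates(ms)
        assert out.loc[0, "E_A1"] == pytest.approx(values.sum() / 9)

    def test_groups_kept_separate(self):
        ms = [self._zi(1.0, 1, 1, thickness=1.0), self._zi(9.0, 1, 1, thickness=2.0)]
        out = average_replicates(ms)
        assert len(out) == 2
        assert sorted(out["E_A2"]) == [1.0, 9.0]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            average_replicates([])
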