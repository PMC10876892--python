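"""Zoning geometry: frames, clock angles, partitions, oracle equivalence."""

import numpy as np
import pytest

from rdmap import anatomy
from rdmap.anatomy import PartitionRule, fit_frame

from conftest import brute_force_geometry


def make_frame(fovea=(64.0, 64.0), disc=(92.0, 64.0), radius=5.0,
               laterality="OD", canvas=(128, 128)):
    return fit_frame(fovea, disc, radius, laterality, canvas)


class TestFitFrame:
    def test_horizontal_frame(self):
        f = fit_frame((256, 256), (320, 256), 20, "OD", (512, 512))
        assert f.rotation_deg == pytest.approx(0.0)
        assert f.posterior_pole_radius == pytest.approx(84.0)

    def test_rotated_frame_compensation(self):
        # disc 45 degrees below-right: calibrated horizontal tilts by +45
        f = fit_frame((256, 256), (320, 320), 20, "OD", (512, 512))
        assert f.rotation_deg == pytest.approx(45.0)
        # a pixel along the fovea->disc direction sits at calibrated 3 o'clock
        assert anatomy.zone_of_point(f, (300, 300)) == "right"
        assert float(anatomy.clock_angle(f, 300, 300)) == pytest.approx(90.0)

    def test_os_rotation_normalized_toward_positive_x(self):
        f = fit_frame((64, 64), (36, 64), 5, "OS", (128, 128))
        assert f.rotation_deg == pytest.approx(0.0)

    def test_mirror_symmetry_swaps_left_right(self):
        n = 128
        cx = (n - 1) / 2.0
        f_od = fit_frame((cx, cx), (cx + 28, cx), 5, "OD", (n, n))
        f_os = fit_frame((cx, cx), (cx - 28, cx), 5, "OS", (n, n))
        swap = {"left": "right", "right": "left",
                "superior": "superior", "inferior": "inferior"}
        rng = np.random.default_rng(0)
        for _ in range(200):
            x = rng.uniform(0, n - 1)
            y = rng.uniform(0, n - 1)
            if abs(x - cx) < 1e-9 and abs(y - cx) < 1e-9:
                continue
            z = anatomy.zone_of_point(f_od, (x, y))
            zm = anatomy.zone_of_point(f_os, ((n - 1) - x, y))
            assert zm == swap[z]

    def test_coincident_landmarks_rejected(self):
        with pytest.raises(ValueError):
            fit_frame((10, 10), (10, 10), 5, "OD", (64, 64))

    def test_bad_laterality_rejected(self):
        with pytest.raises(ValueError):
            fit_frame((10, 10), (30, 10), 5, "LEFT", (64, 64))


class TestZones:
    @pytest.mark.parametrize(
        "theta,zone",
        [
            (0.0, "superior"),
            (30.0, "superior"),
            (90.0, "right"),
            (180.0, "inferior"),
            (270.0, "left"),
            (300.0, "superior"),
            (359.9, "superior"),
            (60.0, "right"),       # 2 o'clock boundary -> clockwise-later zone
            (120.0, "inferior"),
            (240.0, "left"),
        ],
    )
    def test_zone_of_angle(self, theta, zone):
        assert anatomy.zone_of_angle(theta) == zone

    def test_zone_at_fovea_rejected(self):
        f = make_frame()
        with pytest.raises(ValueError):
            anatomy.zone_of_point(f, f.fovea)

    def test_cardinal_points(self):
        f = make_frame()
        fx, fy = f.fovea
        assert anatomy.zone_of_point(f, (fx, fy - 10)) == "superior"
        assert anatomy.zone_of_point(f, (fx + 10, fy)) == "right"
        assert anatomy.zone_of_point(f, (fx, fy + 10)) == "inferior"
        assert anatomy.zone_of_point(f, (fx - 10, fy)) == "left"


class TestPosteriorPole:
    def test_disc_inside_circle(self):
        f = make_frame()
        mask = anatomy.posterior_pole_mask(f)
        dx, dy = f.disc_center
        r = f.disc_radius
        for px, py in [(dx + r - 1, dy), (dx - r + 1, dy), (dx, dy + r - 1)]:
            assert mask[int(round(py)), int(round(px))]

    def test_area_close_to_analytic(self):
        f = make_frame()
        area = int(anatomy.posterior_pole_mask(f).sum())
        r = f.posterior_pole_radius
        assert abs(area - np.pi * r * r) < 4 * r

    def test_pixel_beyond_radius_outside(self):
        f = make_frame()
        mask = anatomy.posterior_pole_mask(f)
        x = int(f.fovea[0] + f.posterior_pole_radius + 1)
        assert not mask[int(f.fovea[1]), x]


class TestPartitionIndex:
    def test_first_sector_inner_ring(self):
        f = make_frame()
        # theta ~= 7 deg, radius well inside the posterior pole
        x = f.fovea[0] + 10 * np.sin(np.radians(7))
        y = f.fovea[1] - 10 * np.cos(np.radians(7))
        assert anatomy.partition_index(f, (x, y)) == 0

    def test_last_sector_outer_ring(self):
        f = make_frame()
        r = f.posterior_pole_radius + 15
        x = f.fovea[0] + r * np.sin(np.radians(350))
        y = f.fovea[1] - r * np.cos(np.radians(350))
        assert anatomy.partition_index(f, (x, y)) == 47

    def test_sector_increment_under_rotation(self):
        f = make_frame()
        r = 20.0
        for k in range(24):
            theta = 3.0 + 15.0 * k
            x = f.fovea[0] + r * np.sin(np.radians(theta))
            y = f.fovea[1] - r * np.cos(np.radians(theta))
            assert anatomy.partition_index(f, (x, y)) == k % 24


class TestPartitionVector:
    def test_exactly_min_pixels_is_zero(self):
        f = make_frame()
        rule = PartitionRule(min_pixels=50, evaluation_resolution=128)
        mask = np.zeros((128, 128), dtype=np.uint8)
        # 50 pixels strictly inside partition 1 (theta in [15, 30), inner ring)
        placed = 0
        for r in range(8, 30):
            for tdeg in np.linspace(16, 29, 12):
                if placed == 50:
                    break
                x = int(round(f.fovea[0] + r * np.sin(np.radians(tdeg))))
                y = int(round(f.fovea[1] - r * np.cos(np.radians(tdeg))))
                if mask[y, x] == 0 and anatomy.partition_index(f, (x, y)) == 1:
                    mask[y, x] = 1
                    placed += 1
        assert placed == 50
        assert anatomy.partition_vector(mask, f, rule).sum() == 0
        # one more pixel flips the bit
        for r in range(8, 40):
            x = int(round(f.fovea[0] + r * np.sin(np.radians(22))))
            y = int(round(f.fovea[1] - r * np.cos(np.radians(22))))
            if mask[y, x] == 0 and anatomy.partition_index(f, (x, y)) == 1:
                mask[y, x] = 1
                break
        vec = anatomy.partition_vector(mask, f, rule)
        assert vec[1] == 1 and vec.sum() == 1

    def test_matches_brute_force_oracle(self):
        f = make_frame()
        rule = PartitionRule(min_pixels=3, evaluation_resolution=128)
        rng = np.random.default_rng(42)
        for _ in range(20):
            mask = (rng.random((128, 128)) < 0.05).astype(np.uint8)
            counts, zone_counts, post = brute_force_geometry(
                mask, f.fovea, f.disc_center, f.disc_radius
            )
            assert anatomy.partition_counts(mask, f).tolist() == counts
            vec = anatomy.partition_vector(mask, f, rule)
            assert vec.tolist() == [int(c > 3) for c in counts]
            assert anatomy.posterior_involved(mask, f, rule) == (post > 3)

    def test_shape_mismatch_rejected(self):
        f = make_frame()
        with pytest.raises(ValueError):
            anatomy.partition_vector(np.zeros((64, 64)), f)


class TestPrimaryZone:
    def test_largest_count_wins(self):
        f = make_frame()
        mask = np.zeros((128, 128), dtype=np.uint8)
        fy = int(f.fovea[1])
        fx = int(f.fovea[0])
        mask[fy - 30 : fy - 20, fx - 5 : fx + 5] = 1  # 100 px superior
        mask[fy - 2 : fy + 2, fx + 20 : fx + 30] = 1  # 40 px right
        assert anatomy.primary_zone(mask, f) == "superior"

    def test_tie_break_order(self):
        f = make_frame()
        mask = np.zeros((128, 128), dtype=np.uint8)
        fy, fx = int(f.fovea[1]), int(f.fovea[0])
        mask[fy - 30 : fy - 20, fx - 5 : fx + 5] = 1  # superior block
        mask[fy + 20 : fy + 30, fx - 5 : fx + 5] = 1  # inferior block, equal
        assert anatomy.primary_zone(mask, f) == "superior"

    def test_empty_mask_none(self):
        f = make_frame()
        assert anatomy.primary_zone(np.zeros((128, 128)), f) is None

    def test_rotation_moves_primary_zone(self):
        f = make_frame()
        for theta, zone in [(30, "superior"), (90, "right"),
                            (180, "inferior"), (270, "left")]:
            mask = np.zeros((128, 128), dtype=np.uint8)
            for r in np.arange(15, 40, 0.8):
                for d in np.arange(theta - 8, theta + 8, 0.8):
                    x = int(round(f.fovea[0] + r * np.sin(np.radians(d))))
                    y = int(round(f.fovea[1] - r * np.cos(np.radians(d))))
                    mask[y, x] = 1
            assert anatomy.primary_zone(mask, f) == zone


class TestTilingInvariants:
    def test_exhaustive_tiling_128(self):
        f = make_frame()
        idx = anatomy.partition_index_map(f)
        assert idx.shape == (128, 128)
        # exactly one partition per non-fovea pixel
        assert ((idx >= 0) & (idx < 48)).sum() == 128 * 128 - 1
        assert (idx == -1).sum() == 1
        # inner-ring union is exactly the posterior-pole circle
        pole = anatomy.posterior_pole_mask(f)
        inner = (idx >= 0) & (idx < 24)
        fovea_px = idx == -1
        assert np.array_equal(inner | fovea_px, pole)
        # zones are unions of their sectors
        yy, xx = np.mgrid[0:128, 0:128]
        sel = idx >= 0
        zones = anatomy.zone_of_angle(anatomy.clock_angle(f, xx[sel], yy[sel]))
        sectors = idx[sel] % 24
        for s in range(24):
            expect = anatomy.zone_of_sector(s)
            got = set(zones[sectors == s].tolist())
            assert got == {expect}

    def test_rotation_equivariance_cyclic_shift(self):
        f = make_frame()
        rule = PartitionRule(min_pixels=3.125, evaluation_resolution=128)
        rr, = [np.hypot(np.arange(128)[None, :] - f.fovea[0],
                        np.arange(128)[:, None] - f.fovea[1])]
        theta = np.degrees(np.arctan2(np.arange(128)[None, :] - f.fovea[0],
                                      -(np.arange(128)[:, None] - f.fovea[1]))) % 360
        base_span = (3.7, 48.7)  # avoid grid-aligned boundaries
        band = (rr > 8) & (rr < 55)

        def wedge(offset):
            lo = (base_span[0] + offset) % 360
            hi = (base_span[1] + offset) % 360
            if lo < hi:
                ang = (theta >= lo) & (theta < hi)
            else:
                ang = (theta >= lo) | (theta < hi)
            return (ang & band).astype(np.uint8)

        v0 = anatomy.partition_vector(wedge(0), f, rule)
        for k in [1, 3, 7, 12]:
            vk = anatomy.partition_vector(wedge(15 * k), f, rule)
            expected = np.concatenate(
                [np.roll(v0[:24], k), np.roll(v0[24:], k)]
            )
            assert np.array_equal(vk, expected), f"shift k={k}"
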