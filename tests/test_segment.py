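"""Segmentation stages against hand-computed and brute-force oracles."""

import numpy as np
import pytest
import scipy.ndimage as ndi

import pollenvia as pv
from pollenvia.segment import (SegmentationConfig, _region_from_mask,
                               detect_regions, extract_grain_regions,
                               gradient_highlight, split_touching,
                               to_grayscale)


def _disk_mask(h, w, cy, cx, r):
    yy, xx = np.mgrid[0:h, 0:w]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r ** 2


class TestToGrayscale:
    @pytest.mark.parametrize("rgb,expected", [
        ((255, 255, 255), 255),
        ((0, 0, 0), 0),
        ((255, 0, 0), 76),    # 0.299 * 255 = 76.245 -> 76
        ((0, 255, 0), 150),   # 0.587 * 255 = 149.685 -> 150
        ((0, 0, 255), 29),    # 0.114 * 255 = 29.07 -> 29
    ])
    def test_luminance_weights(self, rgb, expected):
        img = np.full((4, 4, 3), rgb, dtype=np.uint8)
        assert np.all(to_grayscale(img) == expected)

    def test_wrong_channel_count_raises(self):
        with pytest.raises(ValueError):
            to_grayscale(np.zeros((4, 4), dtype=np.uint8))
        with pytest.raises(ValueError):
            to_grayscale(np.zeros((4, 4, 4), dtype=np.uint8))


class TestGradientHighlight:
    def test_constant_image_is_zero(self):
        assert np.all(gradient_highlight(np.full((8, 8), 77,
                                                 dtype=np.uint8)) == 0)

    def test_vertical_step_magnitude(self):
        """Unnormalized 3x3 Sobel across a 0->255 step: brute-force
        correlation on a 5x5 patch gives |Gx| = 1020 at the step columns."""
        img = np.zeros((5, 10), dtype=np.uint8)
        img[:, 5:] = 255
        kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]])
        patch = img[1:4, 3:8].astype(float)
        brute = abs(np.sum(kx * patch[:, 1:4]))  # centered at column 5
        assert brute == 1020
        mag = gradient_highlight(img)
        assert mag[2, 4] == 1020 and mag[2, 5] == 1020

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, size=(12, 17)).astype(np.uint8)
        assert np.allclose(gradient_highlight(img.T),
                           gradient_highlight(img).T)

    def test_empty_image_raises(self):
        with pytest.raises(ValueError):
            gradient_highlight(np.zeros((0, 0)))


class TestDetectRegions:
    def test_blank_image_empty_mask(self):
        mask = detect_regions(np.full((64, 64), 200, dtype=np.uint8))
        assert not mask.any()

    def test_single_disk_one_component(self):
        img = np.full((101, 101), 220, dtype=np.uint8)
        img[_disk_mask(101, 101, 50, 50, 30)] = 80
        mask = detect_regions(img)
        _, n = ndi.label(mask)
        assert n == 1

    def test_closing_bridges_outline_gap(self):
        """A disk outline with a 2 px gap: raw edges leave the interior
        unfilled; after closing the loop is bridged and filled."""
        img = np.full((101, 101), 220, dtype=np.uint8)
        ring = _disk_mask(101, 101, 50, 50, 30) & \
            ~_disk_mask(101, 101, 50, 50, 27)
        ring[49:52, 78:81] = False  # cut a small gap in the outline
        img[ring] = 60
        mask = detect_regions(img, SegmentationConfig())
        # the filled area must cover most of the disk interior
        interior = _disk_mask(101, 101, 50, 50, 25)
        assert mask[interior].mean() > 0.9

    def test_bad_canny_thresholds_rejected(self):
        with pytest.raises(ValueError):
            detect_regions(np.zeros((8, 8), dtype=np.uint8),
                           SegmentationConfig(canny_low=100, canny_high=50))


class TestSplitTouching:
    def test_single_disk_one_label(self):
        mask = _disk_mask(101, 101, 50, 50, 25)
        labels = split_touching(mask)
        assert labels.max() == 1

    def test_disjoint_disks_stay_separate(self):
        mask = _disk_mask(121, 201, 60, 50, 20) | \
            _disk_mask(121, 201, 60, 130, 20)
        labels = split_touching(mask)
        assert labels.max() == 2

    @pytest.mark.parametrize("factor", [1.2, 1.4, 1.6, 1.8, 1.9])
    def test_overlapping_disks_split_into_two(self, factor):
        """Analytic two-circle masks with center distance 1.2r..1.9r."""
        r = 20
        d = int(round(factor * r))
        mask = _disk_mask(101, 161, 50, 50, r) | \
            _disk_mask(101, 161, 50, 50 + d, r)
        _, n_comp = ndi.label(mask)
        assert n_comp == 1  # genuinely touching
        labels = split_touching(mask)
        assert labels.max() == 2

    def test_empty_mask(self):
        labels = split_touching(np.zeros((10, 10), dtype=bool))
        assert labels.max() == 0 and labels.shape == (10, 10)


class TestExtractGrainRegions:
    def test_disk_kept_with_exact_area(self, disk_mask):
        """Digitized radius-20 disk: area equals the brute-force pixel count
        of x^2+y^2 <= r^2, perimeter within 10% of 2*pi*r, kept by filter."""
        labeled = disk_mask.astype(np.int32)
        regions = extract_grain_regions(labeled)
        assert len(regions) == 1
        reg = regions[0]
        assert reg.area_px == disk_mask.sum() == 1257
        assert abs(reg.perimeter_px - 2 * np.pi * 20) / (2 * np.pi * 20) < 0.10
        assert 0.85 <= reg.circularity <= 1.1

    def test_small_rectangle_discarded_by_area(self):
        """9x11 px rectangle has area 99 <= 100 -> discarded despite being
        compact."""
        labeled = np.zeros((40, 40), dtype=np.int32)
        labeled[10:19, 10:21] = 1
        assert (labeled == 1).sum() == 99
        assert extract_grain_regions(labeled) == []

    def test_elongated_bar_discarded_by_circularity(self):
        """3x200 bar: ideal circularity 4*pi*600/406^2 ~ 0.046 < 0.5."""
        labeled = np.zeros((20, 220), dtype=np.int32)
        labeled[8:11, 10:210] = 1
        region = _region_from_mask(labeled == 1, (0, 0), 1)
        ideal = 4 * np.pi * 600 / 406 ** 2
        assert abs(region.circularity - ideal) / ideal < 0.10
        assert extract_grain_regions(labeled) == []

    def test_border_policy(self):
        labeled = np.zeros((60, 60), dtype=np.int32)
        labeled[_disk_mask(60, 60, 0, 30, 15)] = 1  # clipped at the border
        assert extract_grain_regions(
            labeled, SegmentationConfig(border_policy="drop")) == []
        kept = extract_grain_regions(
            labeled, SegmentationConfig(border_policy="keep",
                                        circularity_min=0.0))
        assert len(kept) == 1

    def test_filter_idempotence(self, default_scene):
        """Re-extracting from the kept regions' own label image changes
        nothing."""
        cfg = SegmentationConfig()
        regions = pv.segment_image(default_scene.image, cfg)
        relabeled = np.zeros(default_scene.image.shape[:2], dtype=np.int32)
        for reg in regions:
            x0, y0, x1, y1 = reg.bbox
            relabeled[y0:y1, x0:x1][reg.pixel_mask] = reg.region_id
        again = extract_grain_regions(relabeled, cfg)
        assert len(again) == len(regions)
        for a, b in zip(again, regions):
            assert a.area_px == b.area_px
            assert a.bbox == b.bbox
            assert abs(a.circularity - b.circularity) < 1e-9

    def test_region_ids_raster_order(self, default_scene):
        regions = pv.segment_image(default_scene.image)
        assert [r.region_id for r in regions] == \
            list(range(1, len(regions) + 1))
        keys = [(r.centroid_xy[1], r.centroid_xy[0]) for r in regions]
        assert keys == sorted(keys)

    def test_determinism(self, default_scene):
        r1 = pv.segment_image(default_scene.image)
        r2 = pv.segment_image(default_scene.image)
        assert len(r1) == len(r2)
        for a, b in zip(r1, r2):
            assert np.array_equal(a.contour, b.contour)
            assert a.area_px == b.area_px and a.bbox == b.bbox


class TestEndToEndSegmentation:
    def test_scene_grain_count_recovered(self, default_scene):
        regions = pv.segment_image(default_scene.image)
        assert len(regions) == len(default_scene.grains)

    def test_invalid_config_rejected(self):
        for bad in (dict(close_kernel_px=4), dict(close_kernel_px=1),
                    dict(border_policy="maybe"),
                    dict(watershed_min_peak_distance_px=0)):
            with pytest.raises(ValueError):
                SegmentationConfig(**bad).validate()
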