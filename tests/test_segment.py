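"""Segmentation primitives against brute-force oracles."""

import numpy as np
import pytest
from skimage.filters import threshold_isodata as skimage_isodata

from clasifish import (
    SegmentationParams,
    maxima_particles,
    median3x3,
    segment_channel,
    split_and_label,
    threshold_bernsen,
    threshold_isodata,
)


class TestMedian3x3:
    def test_constant_unchanged(self):
        img = np.full((8, 8), 7.0)
        assert np.array_equal(median3x3(img), img)

    def test_hot_pixel_removed(self):
        img = np.zeros((9, 9))
        img[4, 4] = 100.0
        assert median3x3(img)[4, 4] == 0.0

    def test_matches_naive_sort_oracle(self, rng):
        img = rng.integers(0, 255, (16, 16)).astype(float)
        out = median3x3(img)
        padded = np.pad(img, 1, mode="edge")
        for y in range(16):
            for x in range(16):
                window = padded[y : y + 3, x : x + 3].ravel()
                assert out[y, x] == np.sort(window)[4]

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            median3x3(np.zeros((2, 5)))


class TestIsoData:
    def test_two_level_fixture(self):
        mask, t = threshold_isodata(np.array([[1, 1, 1], [9, 9, 9]]))
        assert t == 5.0
        assert np.array_equal(mask, np.array([[0, 0, 0], [1, 1, 1]], bool))

    def test_two_distinct_values_threshold_at_midpoint(self):
        mask, t = threshold_isodata(np.array([[2, 8], [2, 8]]))
        assert t == 5.0

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            threshold_isodata(np.full((4, 4), 3))

    def test_fixed_point_matches_exhaustive_search(self, rng):
        """The converged threshold satisfies the intermeans fixed point found
        by exhaustive search over all candidate thresholds."""
        values = np.concatenate(
            [rng.normal(40, 6, 400), rng.normal(160, 20, 200)]
        ).reshape(20, 30)
        _, t = threshold_isodata(values)
        step = (values.max() - values.min()) / 256  # quantization gray level
        # exhaustive search: the candidate minimizing |intermeans(c) - c|
        grid = np.linspace(values.min(), values.max(), 2000)[1:-1]
        devs = []
        for c in grid:
            low, high = values[values <= c], values[values > c]
            devs.append(abs(0.5 * (low.mean() + high.mean()) - c))
        best = grid[int(np.argmin(devs))]
        assert abs(t - best) <= max(step, 1.0)
        # and t is itself (approximately) a fixed point on the raw values
        low, high = values[values <= t], values[values > t]
        assert abs(0.5 * (low.mean() + high.mean()) - t) <= max(step, 1.0)

    def test_agrees_with_skimage_on_integer_image(self, rng):
        img = np.concatenate(
            [rng.integers(0, 60, 500), rng.integers(150, 255, 300)]
        ).reshape(40, 20).astype(np.uint8)
        _, t = threshold_isodata(img)
        ref = skimage_isodata(img)
        assert abs(t - ref) <= 2.0


class TestBernsen:
    def test_hand_computed_window(self):
        # centre sees min 10 / max 200 -> mid-gray 105; 120 >= 105 and the
        # contrast 190 clears the threshold, so the centre is foreground
        img = np.full((5, 5), 120.0)
        img[1, 2] = 10.0
        img[3, 2] = 200.0
        out = threshold_bernsen(img, radius=2, contrast_threshold=15)
        assert out[2, 2]

    def test_flat_dark_region_is_background(self):
        img = np.zeros((10, 10))
        img[0, 0] = 100.0  # sets the dynamic range
        out = threshold_bernsen(img, radius=2, contrast_threshold=15)
        assert not out[5:, 5:].any()

    def test_matches_naive_double_loop(self, rng):
        img = rng.integers(0, 255, (32, 32)).astype(float)
        radius, contrast = 3, 15.0
        out = threshold_bernsen(img, radius=radius, contrast_threshold=contrast)
        half_range = 0.5 * (img.max() + img.min())
        for y in range(32):
            for x in range(32):
                vals = []
                for dy in range(-radius, radius + 1):
                    for dx in range(-radius, radius + 1):
                        if dy * dy + dx * dx <= radius * radius:
                            yy = min(max(y + dy, 0), 31)
                            xx = min(max(x + dx, 0), 31)
                            vals.append(img[yy, xx])
                lo, hi = min(vals), max(vals)
                mid = 0.5 * (lo + hi)
                if hi - lo >= contrast:
                    expect = img[y, x] >= mid
                else:
                    expect = mid >= half_range
                assert out[y, x] == expect, (y, x)


def two_blobs(separation, sigma=3.0, size=64):
    yy, xx = np.mgrid[0:size, 0:size]
    c = size // 2
    g1 = np.exp(-(((yy - c) ** 2 + (xx - c + separation / 2) ** 2) / (2 * sigma**2)))
    g2 = np.exp(-(((yy - c) ** 2 + (xx - c - separation / 2) ** 2) / (2 * sigma**2)))
    return 100.0 * (g1 + g2)


class TestMaximaParticles:
    def test_two_separated_blobs_two_particles(self):
        img = two_blobs(separation=30)
        boundary = maxima_particles(img, prominence=10)
        labels, n = __import__("scipy.ndimage", fromlist=["label"]).label(~boundary)
        assert boundary.any()
        assert n == 2

    def test_single_blob_no_boundary(self):
        img = two_blobs(separation=0)
        assert not maxima_particles(img, prominence=10).any()

    def test_saddle_depth_controls_splitting(self):
        """Prominence above/below the lower peak's dynamics merges/splits.

        Unequal merged blobs: the lower maximum's prominence is its height
        above the saddle toward the higher maximum, read off the profile.
        """
        size, sep, sigma = 64, 10, 3.0
        yy, xx = np.mgrid[0:size, 0:size]
        c = size // 2
        g1 = np.exp(-(((yy - c) ** 2 + (xx - c + sep / 2) ** 2) / (2 * sigma**2)))
        g2 = np.exp(-(((yy - c) ** 2 + (xx - c - sep / 2) ** 2) / (2 * sigma**2)))
        img = 100.0 * g1 + 70.0 * g2
        row = img[c]
        peaks = [x for x in range(1, size - 1) if row[x - 1] < row[x] > row[x + 1]]
        assert len(peaks) == 2
        lower_peak = min(row[x] for x in peaks)
        saddle = row[min(peaks) : max(peaks) + 1].min()
        dynamics = lower_peak - saddle
        assert dynamics > 1.0  # blobs genuinely merged but dimpled
        merged = maxima_particles(img, prominence=dynamics * 1.5)
        split = maxima_particles(img, prominence=dynamics * 0.5)
        assert not merged.any()
        assert split.any()

    def test_invalid_prominence(self):
        with pytest.raises(ValueError):
            maxima_particles(np.zeros((8, 8)), prominence=0)


class TestSplitAndLabel:
    def params(self, min_area=0.0):
        return SegmentationParams(min_object_area_um2=min_area)

    def test_boundary_bisects_rectangle(self):
        mask = np.zeros((8, 6), bool)
        mask[2:6, 1:5] = True
        boundary = np.zeros_like(mask)
        boundary[:, 3] = True
        out = split_and_label(mask, boundary, self.params(), pixel_size_um=1.0)
        assert out.n_labels == 2

    def test_empty_mask_zero_labels(self):
        out = split_and_label(
            np.zeros((5, 5), bool), np.zeros((5, 5), bool), self.params(), 1.0
        )
        assert out.n_labels == 0

    def test_min_area_removal_matches_bruteforce(self, rng):
        from scipy import ndimage

        mask = rng.random((64, 64)) < 0.15
        none = np.zeros_like(mask)
        min_area = 4.0  # px^2 at pixel size 1 um
        out = split_and_label(
            mask, none, self.params(min_area=min_area), pixel_size_um=1.0
        )
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        lab, n = ndimage.label(mask, structure=structure)
        sizes = np.bincount(lab.ravel())[1:]
        assert out.n_labels == int((sizes >= min_area).sum())
        # labels renumbered contiguously
        kept = np.unique(out.labels)
        assert np.array_equal(kept, np.arange(out.n_labels + 1))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            split_and_label(
                np.zeros((4, 4), bool), np.zeros((5, 5), bool), self.params(), 1.0
            )

    def test_labels_partition_foreground(self, rng):
        img = two_blobs(separation=12) + rng.normal(0, 1, (64, 64))
        mask = img > 30
        boundary = maxima_particles(img, prominence=5)
        out = split_and_label(mask, boundary, self.params(), 1.0)
        assert ((out.labels > 0) <= mask).all()  # union of labels inside mask


class TestSegmentChannel:
    def test_deterministic_and_reported(self):
        img = two_blobs(separation=30) + 1.0
        labels1, rep1 = segment_channel(img, "isodata", SegmentationParams(), 0.1)
        labels2, rep2 = segment_channel(img, "isodata", SegmentationParams(), 0.1)
        assert np.array_equal(labels1.labels, labels2.labels)
        assert rep1["threshold"] == rep2["threshold"]
        assert rep1["n_objects"] == labels1.n_labels == 2

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            segment_channel(np.zeros((8, 8)), "otsu", SegmentationParams(), 0.1)
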