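import numpy as np
import pytest

from hyperleaf.cube_io import HyperspectralCube, WavelengthAxis
from hyperleaf.roi import (
    AUGMENTATION_OPS,
    LeafSample,
    augment_set,
    extract_mean_spectrum,
    otsu_threshold,
    pad_center,
    partition_dataset,
    segment_leaf,
    split_subblocks,
    subblock_windows,
)
from hyperleaf.synthleaf import simulate_leaf


def brute_force_otsu(image, nbins=256):
    """Independent oracle: exhaustive search over all histogram cut points."""
    counts, edges = np.histogram(
        image.ravel(), bins=nbins, range=(image.min(), image.max())
    )
    centers = 0.5 * (edges[:-1] + edges[1:])
    best_k, best_v = None, -np.inf
    total = counts.sum()
    for k in range(nbins - 1):
        w0 = counts[: k + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[: k + 1] * centers[: k + 1]).sum() / w0
        mu1 = (counts[k + 1:] * centers[k + 1:]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v + 1e-12:
            best_v, best_k = v, k
    return float(edges[best_k + 1])


class TestOtsu:
    def test_bimodal_image_split_between_modes(self):
        img = np.concatenate([np.full(50, 0.1), np.full(50, 0.9)])
        t = otsu_threshold(img.reshape(10, 10))
        assert 0.1 < t < 0.9

    def test_matches_exhaustive_oracle_on_random_images(self, rng):
        for _ in range(25):
            img = rng.uniform(0, 1, size=(8, 8))
            assert otsu_threshold(img) == pytest.approx(brute_force_otsu(img))

    def test_constant_image_is_an_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            otsu_threshold(np.full((5, 5), 0.3))


class TestSegmentLeaf:
    def _cube_with_nir_indicator(self, indicator):
        """Cube whose 800 nm band is `indicator`, other bands flat."""
        axis = WavelengthAxis([700.0, 800.0, 900.0])
        H, W = indicator.shape
        data = np.full((H, W, 3), 0.05, np.float32)
        data[:, :, 1] = indicator
        return HyperspectralCube(data, axis)

    def test_square_indicator_recovered_exactly(self):
        indicator = np.full((40, 40), 0.02, np.float32)
        indicator[10:30, 5:25] = 0.9
        mask = segment_leaf(self._cube_with_nir_indicator(indicator))
        assert np.array_equal(mask.astype(bool), indicator > 0.5)

    def test_largest_component_wins(self):
        indicator = np.full((60, 60), 0.02, np.float32)
        indicator[5:35, 5:35] = 0.9    # 900 px blob
        indicator[50:55, 50:55] = 0.9  # 25 px blob
        mask = segment_leaf(self._cube_with_nir_indicator(indicator))
        assert mask[10, 10] == 1 and mask[52, 52] == 0

    def test_simulated_leaves_recovered_with_high_jaccard(self):
        axis = WavelengthAxis.uniform(400, 1000, 24)
        for seed in range(5):
            cube, truth = simulate_leaf(1, axis, size=96, seed=seed)
            mask = segment_leaf(cube).astype(bool)
            truth = truth.astype(bool)
            jacc = (mask & truth).sum() / (mask | truth).sum()
            assert jacc >= 0.95

    def test_empty_scene_is_an_error(self, rng):
        axis = WavelengthAxis([700.0, 800.0, 900.0])
        data = rng.normal(0.5, 0.001, size=(30, 30, 3)).astype(np.float32)
        data[0, 0, 1] = 0.9  # a single bright pixel: < 0.5% foreground
        with pytest.raises(ValueError, match="no leaf"):
            segment_leaf(HyperspectralCube(data, axis))


class TestMeanSpectrum:
    def test_single_pixel_mask(self, random_cube):
        mask = np.zeros(random_cube.shape[:2], np.uint8)
        mask[2, 3] = 1
        assert np.allclose(
            extract_mean_spectrum(random_cube, mask), random_cube.data[2, 3]
        )

    def test_constant_cube(self, small_axis):
        cube = HyperspectralCube(
            np.full((4, 4, len(small_axis)), 0.7, np.float32), small_axis
        )
        assert np.allclose(
            extract_mean_spectrum(cube, np.ones((4, 4))), 0.7, atol=1e-6
        )

    def test_matches_hand_summed_means(self, rng):
        axis = WavelengthAxis([500.0, 600.0])
        data = rng.uniform(size=(3, 3, 2)).astype(np.float32)
        cube = HyperspectralCube(data, axis)
        got = extract_mean_spectrum(cube, np.ones((3, 3)))
        expected = [data[:, :, b].sum() / 9 for b in range(2)]
        assert np.allclose(got, expected, atol=1e-6)

    def test_empty_mask_is_an_error(self, random_cube):
        with pytest.raises(ValueError):
            extract_mean_spectrum(random_cube, np.zeros(random_cube.shape[:2]))


class TestSubblocks:
    def test_stated_window_arithmetic(self):
        # L=100, k=2, overlap=0.25: windows of length 58, shared 16 -> 0.276
        windows = subblock_windows(100, 2, 0.25)
        assert windows == [(0, 58), (42, 100)]
        shared = windows[0][1] - windows[1][0]
        assert shared / 58 == pytest.approx(16 / 58)
        assert shared / 58 < 0.30

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_overlap_below_cap_and_full_coverage(self, k):
        for L in range(50, 301):
            windows = subblock_windows(L, k, 0.25)
            Lw = windows[0][1] - windows[0][0]
            for (s1, e1), (s2, e2) in zip(windows, windows[1:]):
                shared = max(0, min(e1, e2) - max(s1, s2))
                assert shared / Lw < 0.30
            assert windows[0][0] == 0 and windows[-1][1] == L
            covered = set()
            for s, e in windows:
                covered.update(range(s, e))
            assert covered == set(range(L))

    def test_k_out_of_range_is_an_error(self):
        with pytest.raises(ValueError):
            subblock_windows(100, 5)
        with pytest.raises(ValueError):
            subblock_windows(100, 1)

    def test_subblocks_carry_provenance(self, rng):
        axis = WavelengthAxis([500.0, 600.0])
        mask = np.zeros((80, 30), np.uint8)
        mask[5:75, 5:25] = 1
        cube = HyperspectralCube(
            rng.uniform(size=(80, 30, 2)).astype(np.float32), axis
        )
        sample = LeafSample(cube, mask, label=3, leaf_id=17)
        blocks = split_subblocks(sample, k=3)
        assert [b.block_index for b in blocks] == [1, 2, 3]
        assert all(b.leaf_id == 17 and b.label == 3 for b in blocks)


class TestPadCenter:
    def _sample(self, h, w, value=0.5):
        axis = WavelengthAxis([500.0, 600.0])
        data = np.full((h, w, 2), value, np.float32)
        return LeafSample(HyperspectralCube(data, axis),
                          np.ones((h, w), np.uint8), 1, 0)

    def test_small_roi_centered_in_zero_frame(self):
        out = pad_center(self._sample(10, 10), size=112)
        assert out.cube.shape == (112, 112, 2)
        nz = np.argwhere(out.mask)
        assert nz.min(axis=0).tolist() == [51, 51]
        assert nz.max(axis=0).tolist() == [60, 60]
        outside = out.cube.data[out.mask == 0]
        assert np.all(outside == 0)

    def test_sum_preserved_without_rescale(self, rng):
        axis = WavelengthAxis([500.0, 600.0])
        data = rng.uniform(size=(20, 30, 2)).astype(np.float32)
        sample = LeafSample(HyperspectralCube(data, axis),
                            np.ones((20, 30), np.uint8), 1, 0)
        out = pad_center(sample, size=112)
        assert np.allclose(out.cube.data.sum(axis=(0, 1)),
                           data.sum(axis=(0, 1)), rtol=1e-5)

    def test_oversized_roi_rescaled_with_aspect(self):
        out = pad_center(self._sample(200, 50), size=112)
        nz = np.argwhere(out.mask)
        h = nz[:, 0].max() - nz[:, 0].min() + 1
        w = nz[:, 1].max() - nz[:, 1].min() + 1
        assert (h, w) == (112, 28)


class TestPartition:
    def _leaves(self, counts=(90, 90, 79, 81, 90, 92)):
        axis = WavelengthAxis([500.0, 600.0])
        cube = HyperspectralCube(np.ones((4, 4, 2), np.float32), axis)
        mask = np.ones((4, 4), np.uint8)
        samples, leaf_id = [], 0
        for label, count in enumerate(counts, start=1):
            for _ in range(count):
                samples.append(LeafSample(cube, mask, label, leaf_id))
                leaf_id += 1
        return samples

    def test_522_leaves_split_within_one_of_nominal(self):
        samples = self._leaves()
        assert len(samples) == 522
        part = partition_dataset(samples, seed=3)
        label_of = {s.leaf_id: s.label for s in samples}
        for label, count in zip(range(1, 7), (90, 90, 79, 81, 90, 92)):
            for fold, ratio in (("train", 0.6), ("validation", 0.2), ("test", 0.2)):
                got = sum(1 for lid in getattr(part, fold) if label_of[lid] == label)
                assert abs(got - count * ratio) <= 1

    def test_same_seed_same_partition(self):
        samples = self._leaves()
        p1 = partition_dataset(samples, seed=5)
        p2 = partition_dataset(samples, seed=5)
        assert p1 == p2

    def test_tiny_class_is_an_error(self):
        samples = self._leaves(counts=(10, 10, 10, 10, 10, 4))
        with pytest.raises(ValueError, match="class"):
            partition_dataset(samples)

    def test_subblocks_rejected(self):
        samples = self._leaves(counts=(6, 6, 6, 6, 6, 6))
        samples[0] = LeafSample(samples[0].cube, samples[0].mask,
                                samples[0].label, samples[0].leaf_id, block_index=1)
        with pytest.raises(ValueError, match="whole-leaf"):
            partition_dataset(samples)


class TestAugmentation:
    def _padded_samples(self, rng, n=4, label=1):
        axis = WavelengthAxis([500.0, 600.0])
        out = []
        for i in range(n):
            data = np.zeros((16, 16, 2), np.float32)
            data[4:12, 6:10] = rng.uniform(0.2, 0.8, size=(8, 4, 2))
            mask = (data[:, :, 0] > 0).astype(np.uint8)
            out.append(LeafSample(HyperspectralCube(data, axis), mask, label, i))
        return out

    def test_count_contract_and_originals_kept(self, rng):
        samples = self._padded_samples(rng, n=4)
        out = augment_set(samples, per_class_target=11, seed=0)
        assert len(out) == 11
        assert all(any(o is s for o in out) for s in samples)

    def test_spatial_ops_preserve_per_band_sums(self, rng):
        samples = self._padded_samples(rng, n=2)
        out = augment_set(samples, per_class_target=10, seed=1)
        source_sums = [s.cube.data.sum(axis=(0, 1), dtype=np.float64)
                       for s in samples]
        for s in out:
            got = s.cube.data.sum(axis=(0, 1), dtype=np.float64)
            assert any(np.allclose(got, src, rtol=1e-5) for src in source_sums)

    def test_rotation_group_property(self, rng):
        a = rng.uniform(size=(6, 6, 3)).astype(np.float32)
        rot90 = AUGMENTATION_OPS[2]
        out = a
        for _ in range(4):
            out = rot90(out)
        assert np.array_equal(out, a)

    def test_spectral_axis_untouched(self, rng):
        samples = self._padded_samples(rng, n=2)
        out = augment_set(samples, per_class_target=8, seed=2)
        for s in out:
            # every augmented image's per-band histogram equals some source's
            key = np.sort(s.cube.data.reshape(-1, 2), axis=0)
            assert any(
                np.allclose(key, np.sort(src.cube.data.reshape(-1, 2), axis=0))
                for src in samples
            )
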