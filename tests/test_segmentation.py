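"""Thresholding against exhaustive-search oracles; morphology laws."""

import itertools

import numpy as np
import pytest
from scipy import ndimage

from hyphacoloc import presets
from hyphacoloc.errors import DegenerateInputError
from hyphacoloc.segmentation import (
    morphological_opening,
    multi_otsu_thresholds,
    otsu_threshold,
    segment_green,
    segment_red,
)
from hyphacoloc.synthetic_scene import make_scene, render, structure_support


# --- independent exhaustive-search oracles (plain loops over the histogram)

def _histogram(values, bins):
    counts, edges = np.histogram(values, bins=bins,
                                 range=(values.min(), values.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return counts, centers


def brute_force_otsu(values, bins=256):
    counts, centers = _histogram(values, bins)
    total = counts.sum()
    best, best_t = -1.0, None
    for k in range(len(centers)):
        n0 = counts[: k + 1].sum()
        n1 = total - n0
        if n0 == 0 or n1 == 0:
            continue
        mu0 = (counts[: k + 1] * centers[: k + 1]).sum() / n0
        mu1 = (counts[k + 1:] * centers[k + 1:]).sum() / n1
        sigma = (n0 / total) * (n1 / total) * (mu0 - mu1) ** 2
        if sigma > best:
            best, best_t = sigma, centers[k]
    return best_t


def oracle_sigma2(values, bins, threshold):
    """Between-class variance of a 2-class split, by direct summation."""
    counts, centers = _histogram(values, bins)
    total = counts.sum()
    k = int(np.argmin(np.abs(centers - threshold)))
    n0 = counts[: k + 1].sum()
    n1 = total - n0
    mu0 = (counts[: k + 1] * centers[: k + 1]).sum() / n0
    mu1 = (counts[k + 1:] * centers[k + 1:]).sum() / n1
    return (n0 / total) * (n1 / total) * (mu0 - mu1) ** 2


def oracle_sigma3(values, bins, pair):
    """Between-class variance of a 3-class split, by direct summation."""
    counts, centers = _histogram(values, bins)
    total = counts.sum()
    mu_total = (counts * centers).sum() / total
    k1, k2 = (int(np.argmin(np.abs(centers - t))) for t in pair)
    slices = [slice(0, k1 + 1), slice(k1 + 1, k2 + 1), slice(k2 + 1, None)]
    return sum(
        (counts[s].sum() / total)
        * ((counts[s] * centers[s]).sum() / counts[s].sum() - mu_total) ** 2
        for s in slices
    )


def assert_optimal_split(values, bins, ours, ref, sigma_fn):
    """Thresholds agree, or both maximize the variance to machine precision."""
    if np.allclose(ours, ref):
        return
    s_ours, s_ref = sigma_fn(values, bins, ours), sigma_fn(values, bins, ref)
    assert s_ours >= s_ref * (1.0 - 1e-12), (ours, ref, s_ours, s_ref)


def brute_force_multi_otsu(values, bins=64):
    counts, centers = _histogram(values, bins)
    total = counts.sum()
    mu_total = (counts * centers).sum() / total
    best, best_pair = -1.0, None
    for k1, k2 in itertools.combinations(range(len(centers) - 1), 2):
        slices = [slice(0, k1 + 1), slice(k1 + 1, k2 + 1), slice(k2 + 1, None)]
        ns = [counts[s].sum() for s in slices]
        if any(n == 0 for n in ns):
            continue
        sigma = sum(
            (n / total) * ((counts[s] * centers[s]).sum() / n - mu_total) ** 2
            for n, s in zip(ns, slices)
        )
        if sigma > best:
            best, best_pair = sigma, (centers[k1], centers[k2])
    return best_pair


class TestOtsu:
    def test_two_point_volume(self):
        values = np.array([0, 0, 255, 255], dtype=np.uint8).reshape(1, 2, 2)
        thr = otsu_threshold(values)
        mask = values > thr.thresholds[0]
        assert mask.sum() == 2 and values[mask].min() == 255

    def test_constant_volume_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            otsu_threshold(np.full((2, 3, 3), 7))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.integers(0, 256, size=50).astype(np.uint8)
        thr = otsu_threshold(values.reshape(1, 5, 10), bins=256)
        assert_optimal_split(values, 256, thr.thresholds[0],
                             brute_force_otsu(values, 256), oracle_sigma2)

    def test_shift_invariance(self):
        rng = np.random.default_rng(3)
        values = rng.random((4, 6, 6))
        t0 = otsu_threshold(values).thresholds[0]
        t1 = otsu_threshold(values + 5.0).thresholds[0]
        assert t1 == pytest.approx(t0 + 5.0, abs=1e-9)


class TestMultiOtsu:
    def test_three_level_partition(self):
        values = np.repeat([0, 128, 255], 10).astype(np.uint8).reshape(3, 2, 5)
        thr = multi_otsu_thresholds(values)
        t1, t2 = thr.thresholds
        binw = 255 / 256
        # cuts separate the three values up to the half-bin quantization of
        # the histogram (ties resolve to the lexicographically smallest pair)
        assert 0 < t1 < 128
        assert 128 - binw <= t2 < 255

    def test_two_distinct_values_degenerate(self):
        values = np.array([0, 0, 1, 1]).reshape(1, 2, 2)
        with pytest.raises(DegenerateInputError):
            multi_otsu_thresholds(values, n_classes=3)

    @pytest.mark.parametrize("seed,bins", [(s, b) for s in range(6) for b in (32, 64)])
    def test_matches_pair_enumeration(self, seed, bins):
        rng = np.random.default_rng(seed)
        values = rng.integers(0, 256, size=200).astype(np.uint8)
        thr = multi_otsu_thresholds(values.reshape(4, 5, 10), bins=bins)
        assert_optimal_split(values, bins, thr.thresholds,
                             brute_force_multi_otsu(values, bins), oracle_sigma3)

    def test_agrees_with_skimage_on_separated_classes(self):
        skfilters = pytest.importorskip("skimage.filters")
        rng = np.random.default_rng(1)
        values = np.concatenate([
            rng.normal(30, 3, 400), rng.normal(120, 5, 300), rng.normal(220, 4, 300)
        ]).clip(0, 255)
        ours = multi_otsu_thresholds(values.reshape(10, 10, 10), bins=256).thresholds
        theirs = skfilters.threshold_multiotsu(values, classes=3, nbins=256)
        binw = (values.max() - values.min()) / 256
        assert abs(ours[0] - theirs[0]) <= 2 * binw
        assert abs(ours[1] - theirs[1]) <= 2 * binw


class TestOpening:
    def test_empty_mask_stays_empty(self):
        assert not morphological_opening(np.zeros((5, 5, 5), bool)).any()

    def test_isolated_voxel_removed_block_interior_survives(self):
        mask = np.zeros((7, 7, 7), bool)
        mask[1, 1, 1] = True
        mask[3:6, 3:6, 3:6] = True
        opened = morphological_opening(mask)
        assert not opened[1, 1, 1]
        assert opened[4, 4, 4]

    @pytest.mark.parametrize("seed", range(5))
    def test_anti_extensive_idempotent_monotone(self, seed):
        rng = np.random.default_rng(seed)
        m1 = rng.random((16, 16, 16)) < 0.4
        m2 = m1 | (rng.random((16, 16, 16)) < 0.2)
        o1 = morphological_opening(m1)
        assert not np.any(o1 & ~m1)  # anti-extensive
        assert np.array_equal(morphological_opening(o1), o1)  # idempotent
        assert not np.any(o1 & ~morphological_opening(m2))  # monotone


class TestChannelPipelines:
    def test_green_noiseless_mask_equals_truth_support(self):
        scene = make_scene(presets.scene_objects_truth(seed=3))
        pair = render(scene, presets.acq_noiseless())
        mask = segment_green(pair.green)
        assert np.array_equal(mask.mask, structure_support(scene, "green"))
        assert mask.provenance == "otsu"
        assert mask.mask.shape == pair.green.shape

    def test_red_noiseless_mask_equals_opened_truth_support(self):
        scene = make_scene(presets.scene_objects_truth(seed=3))
        pair = render(scene, presets.acq_noiseless())
        mask = segment_red(pair.red)
        support = structure_support(scene, "red")
        expected = ndimage.binary_opening(
            support, ndimage.generate_binary_structure(3, 1))
        assert np.array_equal(mask.mask, expected)
        assert not np.any(mask.mask & ~support)

    def test_red_opened_mask_subset_of_unopened(self, standard_pair):
        opened = segment_red(standard_pair.red)
        raw = segment_red(standard_pair.red, apply_opening=False)
        assert not np.any(opened.mask & ~raw.mask)

    def test_degenerate_channels_propagate(self):
        const = np.full((2, 4, 4), 3.0)
        with pytest.raises(DegenerateInputError):
            segment_green(const)
        two_level = np.zeros((2, 4, 4))
        two_level[0] = 1.0
        with pytest.raises(DegenerateInputError):
            segment_red(two_level)
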