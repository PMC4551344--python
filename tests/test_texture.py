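"""Projection, masking, GLCM parameters and the decay-distance fit."""

import math

import numpy as np
import pytest

from stromasig.texture import (
    DIRECTIONS,
    PARAMETERS,
    auto_mask,
    decay_fit,
    depth_profile,
    glcm_profile,
    max_projection,
)

# direction label -> unit offset (row, col); distances scale the offset with
# per-component rounding (euclidean distance convention)
_OFFSETS = {0: (0.0, 1.0),
            45: (math.sin(math.radians(45)), math.cos(math.radians(45))),
            90: (1.0, 0.0),
            135: (math.sin(math.radians(135)), math.cos(math.radians(135)))}


def brute_force_glcm(img, mask, distance, direction, levels):
    """Symmetric masked co-occurrence counts by double loop (oracle)."""
    dr = round(_OFFSETS[direction][0] * distance)
    dc = round(_OFFSETS[direction][1] * distance)
    h, w = img.shape
    P = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                P[img[r, c], img[r2, c2]] += 1
                P[img[r2, c2], img[r, c]] += 1
    return P


def props_from_glcm(P):
    """The five Haralick parameters of a normalized co-occurrence matrix."""
    p = P / P.sum()
    i, j = np.indices(p.shape, dtype=float)
    contrast = (p * (i - j) ** 2).sum()
    energy = (p ** 2).sum()
    homogeneity = (p / (1 + (i - j) ** 2)).sum()
    entropy = -(p[p > 0] * np.log(p[p > 0])).sum()
    mu_i, mu_j = (p * i).sum(), (p * j).sum()
    si = math.sqrt((p * (i - mu_i) ** 2).sum())
    sj = math.sqrt((p * (j - mu_j) ** 2).sum())
    if si * sj == 0:
        corr = 1.0
    else:
        corr = (p * (i - mu_i) * (j - mu_j)).sum() / (si * sj)
    return {"contrast": contrast, "correlation": corr, "energy": energy,
            "homogeneity": homogeneity, "entropy": entropy}


class TestMaxProjection:
    def test_single_slice_identity(self):
        img = np.arange(12).reshape(3, 4)
        assert np.array_equal(max_projection(img[None]), img)

    def test_matches_per_pixel_loop(self):
        rng = np.random.default_rng(0)
        stack = rng.integers(0, 255, size=(8, 6, 7))
        mp = max_projection(stack)
        for r in range(6):
            for c in range(7):
                assert mp[r, c] == max(stack[z, r, c] for z in range(8))

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            max_projection(np.empty((0, 4, 4)))


class TestAutoMask:
    def test_half_bright_half_dark(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        img[:, 5:] = 255
        _, area = auto_mask(img)
        assert area == pytest.approx(50.0)

    def test_blank_image_empty_mask(self):
        with pytest.warns(UserWarning):
            mask, area = auto_mask(np.zeros((8, 8), dtype=np.uint8))
        assert area == 0.0 and not mask.any()


class TestGlcmProfile:
    def test_constant_foreground_degenerate_values(self):
        img = np.zeros((12, 12), dtype=np.uint8)
        img[2:10, 2:10] = 200
        mask = img > 0
        prof = glcm_profile(img, mask=mask, distances=[1, 2, 3], levels=8)
        v = prof.values.set_index(["parameter", "direction", "distance"])["value"]
        for d in (1, 2, 3):
            for ang in DIRECTIONS:
                assert v[("contrast", ang, d)] == pytest.approx(0.0)
                assert v[("energy", ang, d)] == pytest.approx(1.0)
                assert v[("homogeneity", ang, d)] == pytest.approx(1.0)

    def test_two_level_toy_image_hand_enumeration(self):
        img = np.array([[0, 0, 1, 1],
                        [0, 1, 1, 0],
                        [1, 1, 0, 0],
                        [1, 0, 0, 1]], dtype=np.uint8)
        mask = np.ones_like(img, dtype=bool)
        prof = glcm_profile(img, mask=mask, distances=[1], levels=2)
        # horizontal neighbor pairs, symmetric: count by hand
        P = brute_force_glcm(img, mask, 1, 0, 2)
        expected = props_from_glcm(P)
        v = prof.values.query("direction == 0 and distance == 1") \
            .set_index("parameter")["value"]
        for name in PARAMETERS:
            assert v[name] == pytest.approx(expected[name], abs=1e-12)

    def test_checkerboard_contrast_alternates_with_distance(self):
        img = np.indices((12, 12)).sum(axis=0) % 2
        img = (img * 255).astype(np.uint8)
        mask = np.ones_like(img, dtype=bool)
        prof = glcm_profile(img, mask=mask, distances=[1, 2], levels=2)
        v = prof.values.set_index(["parameter", "direction", "distance"])["value"]
        # horizontal pairs at distance 1 always differ; at distance 2 identical
        assert v[("contrast", 0, 1)] == pytest.approx(1.0)
        assert v[("contrast", 0, 2)] == pytest.approx(0.0)

    def test_matches_brute_force_on_random_masked_images(self):
        rng = np.random.default_rng(1)
        for trial in range(4):
            img = rng.integers(0, 6, size=(14, 16)).astype(np.uint8)
            mask = rng.uniform(size=img.shape) > 0.3
            prof = glcm_profile(img, mask=mask, distances=[1, 3, 5], levels=6)
            v = prof.values.set_index(["parameter", "direction", "distance"])["value"]
            # the implementation quantizes in-mask intensities; with values
            # 0..5 and levels=6 the quantization is the identity
            for d in (1, 3, 5):
                for ang in DIRECTIONS:
                    P = brute_force_glcm(img, mask, d, ang, 6)
                    if P.sum() == 0:
                        assert np.isnan(v[("contrast", ang, d)])
                        continue
                    expected = props_from_glcm(P)
                    for name in PARAMETERS:
                        assert v[(name, ang, d)] == pytest.approx(
                            expected[name], abs=1e-10), (name, ang, d)

    def test_rotation_permutes_directions_but_not_average(self):
        rng = np.random.default_rng(2)
        img = rng.integers(0, 8, size=(15, 15)).astype(np.uint8)
        mask = np.ones_like(img, dtype=bool)
        a = glcm_profile(img, mask=mask, distances=[1, 2], levels=8)
        b = glcm_profile(np.rot90(img), mask=mask, distances=[1, 2], levels=8)
        for name in PARAMETERS:
            assert np.allclose(a.curve(name), b.curve(name), atol=1e-10)

    def test_image_smaller_than_distance_rejected(self):
        with pytest.raises(ValueError):
            glcm_profile(np.zeros((5, 5), dtype=np.uint8),
                         mask=np.ones((5, 5), bool), distances=[10])


class TestDecayFit:
    d = np.arange(1, 101, dtype=float)

    def test_single_exponential_recovered(self):
        fit = decay_fit(3.0 * np.exp(-self.d / 5.0), self.d, seed=0)
        assert fit.weighted_mean_decay_distance == pytest.approx(5.0, rel=0.01)

    def test_double_exponential_weighted_mean(self):
        y = np.exp(-self.d / 2.0) + np.exp(-self.d / 10.0)
        fit = decay_fit(y, self.d, seed=0)
        # (1*2 + 1*10) / 2 = 6 by the amplitude-weighted definition
        assert fit.weighted_mean_decay_distance == pytest.approx(6.0, rel=0.01)

    def test_noisy_recovery_within_tolerance(self):
        rng = np.random.default_rng(3)
        estimates = []
        for seed in range(20):
            y = np.exp(-self.d / 2.0) + np.exp(-self.d / 10.0)
            noisy = y + 0.01 * np.ptp(y) * rng.normal(size=y.size)
            fit = decay_fit(noisy, self.d, seed=seed)
            estimates.append(fit.weighted_mean_decay_distance)
        assert abs(np.median(estimates) - 6.0) / 6.0 < 0.15

    def test_rising_curve_fit_on_reflection(self):
        y = 2.0 - np.exp(-self.d / 7.0)
        fit = decay_fit(y, self.d, seed=1)
        assert fit.inverted
        assert fit.weighted_mean_decay_distance == pytest.approx(7.0, rel=0.05)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            decay_fit(np.ones(5), np.arange(1.0, 6.0))


class TestDepthProfile:
    def test_uniform_foreground_everywhere(self):
        stack = np.full((4, 6, 6), 100, dtype=np.uint8)
        prof = depth_profile(stack)
        assert np.allclose(prof.percents, 100.0)

    def test_total_is_sum_of_slices(self):
        rng = np.random.default_rng(5)
        stack = rng.integers(0, 255, size=(5, 10, 10)).astype(np.uint8)
        prof = depth_profile(stack, threshold_rule=100.0)
        assert prof.total == prof.counts.sum()
        assert prof.total == int((stack > 100).sum())

    def test_known_per_slice_areas(self):
        stack = np.zeros((2, 10, 10), dtype=np.uint8)
        stack[0, :1, :] = 255   # 10% of slice 0
        stack[1, :3, :] = 255   # 30% of slice 1
        prof = depth_profile(stack, threshold_rule=128.0)
        assert np.allclose(prof.percents, [10.0, 30.0])
        assert prof.total == 40

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            depth_profile(np.empty((0, 3, 3)))
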