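"""Scale-space detector: pyramids, extrema, refinement, orientation.

Oracles: closed-form Gaussian kernels for pyramid levels, a brute-force
26-neighbour scan for extrema, an analytic quadratic patch for sub-pixel
refinement, and synthetic ramps/edges for orientation and edge rejection.
"""

import itertools

import numpy as np
import pytest

from fmritemplate import (
    DoGPyramid,
    FeatureParams,
    Keypoint,
    assign_orientation,
    build_dog_pyramid,
    build_gaussian_pyramid,
    detect_extrema,
    detect_features,
    edge_response_filter,
    refine_keypoint,
)
from fmritemplate.scale_space_features import auto_num_octaves


def _gaussian_kernel_2d(shape, centre, sigma):
    xs, ys = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                         indexing="ij")
    g = np.exp(-((xs - centre[0]) ** 2 + (ys - centre[1]) ** 2)
               / (2.0 * sigma * sigma))
    return g / (2.0 * np.pi * sigma * sigma)


def _brute_force_extrema(dog, border=5):
    """Independent 26-neighbour scan (python loops, no filters)."""
    found = []
    for o, levels in enumerate(dog.octaves):
        stack = np.stack(levels)
        n, h, w = stack.shape
        for lvl in range(1, n - 1):
            for x in range(border, h - border):
                for y in range(border, w - border):
                    v = stack[lvl, x, y]
                    neigh = [
                        stack[lvl + dl, x + dx, y + dy]
                        for dl, dx, dy in itertools.product((-1, 0, 1),
                                                            repeat=3)
                        if (dl, dx, dy) != (0, 0, 0)
                    ]
                    if v > max(neigh) or v < min(neigh):
                        found.append((o, lvl, x, y))
    return found


class TestGaussianPyramid:
    def test_constant_image_stays_constant(self):
        gp = build_gaussian_pyramid(np.full((32, 32), 0.7))
        for levels in gp.octaves:
            for lvl in levels:
                assert np.allclose(lvl, 0.7, atol=1e-12)

    def test_impulse_matches_closed_form_kernel(self):
        img = np.zeros((65, 65))
        img[32, 32] = 1.0
        gp = build_gaussian_pyramid(img, num_octaves=1)
        for j, lvl in enumerate(gp.octaves[0]):
            expected = _gaussian_kernel_2d((65, 65), (32, 32), gp.sigmas[j])
            rms = np.sqrt(np.mean((lvl - expected) ** 2))
            assert rms < 1e-3, f"level {j}: rms {rms}"

    def test_auto_octave_rule(self):
        # floor(log2(96)) - 2 = 4
        assert auto_num_octaves((96, 96)) == 4
        gp = build_gaussian_pyramid(np.zeros((96, 96)))
        assert len(gp.octaves) == 4

    def test_octave_downsampling_halves_size(self):
        gp = build_gaussian_pyramid(np.random.default_rng(0).random((64, 64)))
        sizes = [levels[0].shape[0] for levels in gp.octaves]
        assert sizes == [64, 32, 16, 8]

    def test_sigma_ladder(self):
        gp = build_gaussian_pyramid(np.zeros((32, 32)), intervals_s=3,
                                    base_sigma=1.6)
        k = 2.0 ** (1.0 / 3.0)
        for j, s in enumerate(gp.sigmas):
            assert s == pytest.approx(1.6 * k ** j)
        assert gp.level_sigma(2, 0) == pytest.approx(1.6 * 4)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            build_gaussian_pyramid(np.zeros((8, 8)))
        with pytest.raises(ValueError):
            build_gaussian_pyramid(np.zeros((32, 32)), num_octaves=6)


class TestDoGPyramid:
    def test_constant_image_gives_zero_dog(self):
        dog = build_dog_pyramid(build_gaussian_pyramid(np.full((32, 32), 3.0)))
        for levels in dog.octaves:
            for lvl in levels:
                assert np.allclose(lvl, 0.0, atol=1e-12)

    def test_level_counts(self):
        gp = build_gaussian_pyramid(np.zeros((32, 32)), intervals_s=3)
        dog = build_dog_pyramid(gp)
        assert all(len(lv) == 6 for lv in gp.octaves)      # s + 3
        assert all(len(lv) == 5 for lv in dog.octaves)     # s + 2

    def test_impulse_dog_matches_kernel_difference(self):
        img = np.zeros((65, 65))
        img[32, 32] = 1.0
        gp = build_gaussian_pyramid(img, num_octaves=1)
        dog = build_dog_pyramid(gp)
        for j, lvl in enumerate(dog.octaves[0]):
            expected = (
                _gaussian_kernel_2d((65, 65), (32, 32), gp.sigmas[j + 1])
                - _gaussian_kernel_2d((65, 65), (32, 32), gp.sigmas[j])
            )
            assert np.sqrt(np.mean((lvl - expected) ** 2)) < 1e-3


class TestExtremaDetection:
    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(5)
        from scipy import ndimage
        img = ndimage.gaussian_filter(rng.normal(size=(48, 48)), 1.0)
        img = (img - img.min()) / (img.max() - img.min())
        dog = build_dog_pyramid(build_gaussian_pyramid(img, num_octaves=2))
        fast = sorted(detect_extrema(dog))
        brute = sorted(_brute_force_extrema(dog))
        assert fast == brute

    def test_blob_found_near_centre(self):
        xs, ys = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        img = np.exp(-((xs - 30.4) ** 2 + (ys - 33.6) ** 2) / (2 * 2.6 ** 2))
        dog = build_dog_pyramid(build_gaussian_pyramid(img))
        central = [c for c in detect_extrema(dog)
                   if c[0] == 0 and abs(c[2] - 30.4) <= 1 and abs(c[3] - 33.6) <= 1]
        assert central, "blob centre not detected"

    def test_constant_image_yields_nothing(self):
        dog = build_dog_pyramid(build_gaussian_pyramid(np.full((32, 32), 1.0)))
        assert detect_extrema(dog) == []

    def test_plateau_ties_excluded(self):
        # piecewise-constant DoG stack: plateau values never strict extrema
        levels = [np.zeros((16, 16)) for _ in range(3)]
        levels[1][6:10, 6:10] = 1.0
        dog = DoGPyramid(octaves=[levels], sigmas=[1.6, 2.0, 2.5],
                         k_factor=2 ** (1 / 3), base_sigma=1.6, intervals=1)
        # every plateau cell has at least one equal neighbour, and the
        # surrounding zeros tie with each other too: nothing is strict
        assert detect_extrema(dog, border=1) == []


class TestRefinement:
    @staticmethod
    def _quadratic_dog(x0, y0, l0):
        """D(l, x, y) = 1 − a(x−x0)² − b(y−y0)² − c(l−l0)², peak interior."""
        xs, ys = np.meshgrid(np.arange(16), np.arange(16), indexing="ij")
        levels = [
            1.0 - 0.02 * (xs - x0) ** 2 - 0.03 * (ys - y0) ** 2
            - 0.05 * (lv - l0) ** 2
            for lv in range(3)
        ]
        return DoGPyramid(octaves=[levels], sigmas=[1.6, 2.0, 2.5, 3.2],
                          k_factor=2 ** (1 / 3), base_sigma=1.6, intervals=1)

    def test_quadratic_peak_recovered_exactly(self):
        dog = self._quadratic_dog(8.3, 7.6, 1.2)
        kp = refine_keypoint(dog, (0, 1, 8, 8), contrast_threshold=0.0,
                             border=2)
        assert kp is not None
        assert kp.x == pytest.approx(8.3, abs=1e-9)
        assert kp.y == pytest.approx(7.6, abs=1e-9)

    def test_symmetric_peak_zero_offset(self):
        dog = self._quadratic_dog(8.0, 8.0, 1.0)
        kp = refine_keypoint(dog, (0, 1, 8, 8), contrast_threshold=0.0,
                             border=2)
        assert kp is not None
        assert abs(kp.x - 8.0) < 0.1 and abs(kp.y - 8.0) < 0.1

    def test_low_contrast_rejected(self):
        dog = self._quadratic_dog(8.0, 8.0, 1.0)
        assert refine_keypoint(dog, (0, 1, 8, 8), contrast_threshold=2.0,
                               border=2) is None


class TestEdgeResponseFilter:
    @staticmethod
    def _dog_from_level(level_img):
        levels = [level_img, level_img, level_img]
        return DoGPyramid(octaves=[levels], sigmas=[1.6, 2.0, 2.5, 3.2],
                          k_factor=2 ** (1 / 3), base_sigma=1.6, intervals=1)

    def test_isotropic_blob_kept(self):
        xs, ys = np.meshgrid(np.arange(17), np.arange(17), indexing="ij")
        blob = np.exp(-((xs - 8) ** 2 + (ys - 8) ** 2) / 8.0)
        dog = self._dog_from_level(blob)
        kp = Keypoint(x=8, y=8, octave=0, level=1, sigma=1.6, sigma_oct=1.6,
                      response=1.0, x_oct=8, y_oct=8)
        # α = β ⇒ ratio 4 < (r+1)²/r for every r > 1
        assert edge_response_filter(dog, kp, r=10.0)
        assert edge_response_filter(dog, kp, r=1.5)

    def test_straight_edge_rejected(self):
        xs, _ = np.meshgrid(np.arange(17), np.arange(17), indexing="ij")
        edge = 1.0 / (1.0 + np.exp(-(xs - 8.0)))  # smooth step along x
        dog = self._dog_from_level(edge)
        kp = Keypoint(x=7, y=8, octave=0, level=1, sigma=1.6, sigma_oct=1.6,
                      response=1.0, x_oct=7, y_oct=8)
        assert not edge_response_filter(dog, kp, r=10.0)

    def test_keep_rate_monotone_in_r(self, phantom64):
        from fmritemplate.io_nifti import normalize_slice
        sl = normalize_slice(phantom64[:, :, 0])
        dog = build_dog_pyramid(build_gaussian_pyramid(sl))
        cands = detect_extrema(dog)
        kps = [refine_keypoint(dog, c, contrast_threshold=0.0) for c in cands]
        kps = [k for k in kps if k is not None]
        rates = [
            sum(edge_response_filter(dog, k, r=r) for k in kps)
            for r in (2.0, 5.0, 10.0, 25.0)
        ]
        assert rates == sorted(rates)


class TestOrientation:
    def test_ramp_gradient_orientation(self):
        # intensity increasing along +x ⇒ gradient direction 0°
        xs, _ = np.meshgrid(np.arange(48, dtype=float), np.arange(48),
                            indexing="ij")
        gp = build_gaussian_pyramid(xs / 48.0, num_octaves=1)
        kp = Keypoint(x=24, y=24, octave=0, level=1, sigma=2.0, sigma_oct=2.0,
                      response=1.0, x_oct=24, y_oct=24)
        okp = assign_orientation(gp, kp)
        ang = min(okp.orientation, 360.0 - okp.orientation)
        assert ang <= 10.0

    def test_rotation_equivariance_quarter_turn(self):
        # the same ramp along +y must rotate the answer by 90°
        _, ys = np.meshgrid(np.arange(48), np.arange(48, dtype=float),
                            indexing="ij")
        gp = build_gaussian_pyramid(ys / 48.0, num_octaves=1)
        kp = Keypoint(x=24, y=24, octave=0, level=1, sigma=2.0, sigma_oct=2.0,
                      response=1.0, x_oct=24, y_oct=24)
        okp = assign_orientation(gp, kp)
        assert abs(okp.orientation - 90.0) <= 10.0

    def test_flat_patch_flagged(self):
        gp = build_gaussian_pyramid(np.full((32, 32), 0.5))
        kp = Keypoint(x=16, y=16, octave=0, level=1, sigma=2.0, sigma_oct=2.0,
                      response=1.0, x_oct=16, y_oct=16)
        okp = assign_orientation(gp, kp)
        assert okp.low_confidence and okp.orientation == 0.0


class TestDetectFeatures:
    def test_deterministic(self, phantom64):
        sl = phantom64[:, :, 0]
        a = detect_features(sl)
        b = detect_features(sl)
        assert len(a) == len(b) > 0
        for ka, kb in zip(a, b):
            assert (ka.x, ka.y, ka.sigma, ka.orientation) == \
                   (kb.x, kb.y, kb.sigma, kb.orientation)

    def test_translation_equivariance(self, phantom64):
        sl = phantom64[:, :, 1]
        dx, dy = 5, 3
        shifted = np.roll(sl, (dx, dy), axis=(0, 1))
        a = detect_features(sl)
        b = detect_features(shifted)
        pos_b = np.array([(k.x, k.y) for k in b])
        interior = [k for k in a
                    if 12 < k.x < 52 - dx and 12 < k.y < 52 - dy]
        assert len(interior) >= 5
        matched = 0
        for k in interior:
            d = np.hypot(pos_b[:, 0] - (k.x + dx), pos_b[:, 1] - (k.y + dy))
            if d.min() <= 0.5:
                matched += 1
        assert matched / len(interior) >= 0.8

    def test_subthreshold_noise_yields_nothing(self):
        rng = np.random.default_rng(7)
        # noise amplitude far below the default contrast threshold after
        # blurring; keep un-normalized scale by adding to a constant
        img = 0.5 + 0.001 * rng.normal(size=(64, 64))
        params = FeatureParams(contrast_threshold=0.2)
        assert detect_features(img, params) == []
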