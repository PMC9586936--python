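"""Differentiable warp, PPM loss/mask, homography regression and blending."""

import numpy as np
import pytest

from flimcoreg import synthetic as syn
from flimcoreg.evaluate import corner_error
from flimcoreg.register import (
    Homography,
    PpmWindow,
    RegressionConfig,
    blend,
    ppm_l1,
    ppm_loss_and_grad,
    ppm_mask,
    regress,
    warp,
    warp_grad,
)


class TestHomography:
    def test_singular_matrix_rejected(self):
        with pytest.raises(ValueError):
            Homography(np.zeros((3, 3)))

    def test_normalised_sets_h33_to_one(self):
        H = Homography(2.0 * np.eye(3)).normalised()
        assert H.matrix[2, 2] == 1.0
        np.testing.assert_allclose(H.matrix, np.eye(3))

    def test_json_round_trip(self, tmp_path):
        H = syn.random_homography(64, rng=5)
        H.to_json(tmp_path / "h.json")
        back = Homography.from_json(tmp_path / "h.json")
        np.testing.assert_allclose(back.matrix, H.normalised().matrix)


class TestWarp:
    def test_identity_is_noop(self, texture64):
        np.testing.assert_allclose(warp(texture64, Homography.identity()), texture64)

    def test_integer_translation_matches_shift_oracle(self, texture64):
        out = warp(texture64, Homography.translation(5, 0))
        shifted = np.zeros_like(texture64)
        shifted[:, 5:] = texture64[:, :-5]
        np.testing.assert_allclose(out, shifted, atol=1e-12)

    def test_composition_within_interpolation_tolerance(self, texture64):
        H1 = syn.random_homography(64, rng=1)
        H2 = syn.random_homography(64, rng=2)
        a = warp(warp(texture64, H1), H2)
        b = warp(texture64, H2 @ H1)
        interior = np.abs(a - b)[8:-8, 8:-8]
        assert 255 * interior.mean() < 2.0

    def test_out_of_bounds_fill_is_zero(self, texture64):
        out = warp(texture64, Homography.translation(30, 0))
        assert np.all(out[:, :29] == 0)

    def test_jacobian_matches_finite_differences(self, texture64):
        target = syn.make_texture(64, seed=9, blur_sigma=2.0)
        H = np.eye(3)
        H[0, 2], H[1, 2] = 1.3, -0.6
        w0, jac = warp_grad(texture64, H)
        eps = 1e-7
        probe = np.s_[20:40, 20:40]
        for i, j in [(0, 0), (0, 2), (1, 2), (2, 0)]:
            Hp, Hm = H.copy(), H.copy()
            Hp[i, j] += eps
            Hm[i, j] -= eps
            fd = (warp(texture64, Hp) - warp(texture64, Hm)) / (2 * eps)
            scale = np.abs(fd[probe]).max()
            assert np.abs(jac[i, j] - fd)[probe].max() < 1e-3 * max(scale, 1e-6)


class TestPpmMask:
    def test_full_window_is_all_ones(self):
        assert ppm_mask(64, PpmWindow(64)).all()

    def test_published_window_geometry(self):
        # 200-px window on 256-px images: 40,000 ones inside a 28-px frame
        mask = ppm_mask(256, PpmWindow(200))
        assert mask.sum() == 40000
        assert not mask[:28].any() and not mask[:, -28:].any()
        assert mask[28, 28] and mask[227, 227]

    def test_symmetric_under_flips(self):
        mask = ppm_mask(64, PpmWindow(40))
        np.testing.assert_array_equal(mask, mask[::-1])
        np.testing.assert_array_equal(mask, mask[:, ::-1])

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError):
            ppm_mask(64, PpmWindow(65))


class TestPpmL1:
    def test_identical_images_give_zero(self, texture64):
        assert ppm_l1(texture64, texture64, ppm_mask(64, 48)) == 0.0

    def test_matches_brute_force_loop(self, rng):
        for _ in range(20):
            a = rng.random((32, 32, 3))
            b = rng.random((32, 32, 3))
            mask = ppm_mask(32, int(rng.integers(8, 33)))
            acc = cnt = 0
            for y in range(32):
                for x in range(32):
                    if mask[y, x]:
                        for c in range(3):
                            acc += abs(a[y, x, c] - b[y, x, c])
                            cnt += 1
            assert ppm_l1(a, b, mask) == pytest.approx(acc / cnt, abs=1e-6)

    def test_single_pixel_arithmetic(self):
        a = np.zeros((256, 256))
        b = np.zeros((256, 256))
        b[128, 128] = 0.5
        assert ppm_l1(a, b, ppm_mask(256, 200)) == pytest.approx(0.5 / 40000)

    def test_empty_mask_rejected(self, rng):
        a = rng.random((16, 16))
        with pytest.raises(ValueError):
            ppm_l1(a, a, np.zeros((16, 16), dtype=bool))


class TestLossGradient:
    def test_matches_central_finite_differences(self):
        # smooth textures; step small enough that bilinear kinks are not crossed
        a = syn.make_texture(48, seed=1, blur_sigma=2.0)
        b = syn.make_texture(48, seed=2, blur_sigma=2.0)
        H = np.eye(3)
        H[0, 2], H[1, 2] = 1.3, -0.7
        H += np.random.default_rng(0).normal(0, 1e-3, (3, 3))
        H[2, 2] = 1.0
        mask = ppm_mask(48, 40)
        _, grad, _ = ppm_loss_and_grad(a, b, H, mask)
        eps = 1e-7
        fd = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                Hp, Hm = H.copy(), H.copy()
                Hp[i, j] += eps
                Hm[i, j] -= eps
                fd[i, j] = (
                    ppm_loss_and_grad(a, b, Hp, mask)[0] - ppm_loss_and_grad(a, b, Hm, mask)[0]
                ) / (2 * eps)
        rel = np.abs(grad - fd) / np.maximum(np.abs(fd), 1e-9)
        assert rel.max() < 1e-3


class TestRegress:
    CFG = RegressionConfig(epochs=120, decay_epoch=60, window=PpmWindow(52), image_side=64)

    def test_self_registration_returns_identity(self, texture64):
        res = regress(texture64, texture64, self.CFG)
        assert corner_error(res.H_final, Homography.identity(), 64) < 0.5

    def test_recovers_known_translation(self, texture64):
        H = Homography.translation(4, -3)
        moving, fixed, _ = syn.make_warped_pair(texture64, H)
        res = regress(moving, fixed, self.CFG)
        assert corner_error(res.H_final, H, 64) < 2.0

    def test_best_loss_never_exceeds_initial(self, texture64):
        H = syn.random_homography(64, rng=3, max_translation_px=4)
        moving, fixed, _ = syn.make_warped_pair(texture64, H, noise_sd=0.02, rng=3)
        res = regress(moving, fixed, self.CFG)
        assert res.loss_trace.min() <= res.loss_trace[0]
        assert len(res.loss_trace) == self.CFG.epochs

    def test_deterministic(self, texture64):
        H = Homography.translation(3, 2)
        moving, fixed, _ = syn.make_warped_pair(texture64, H)
        r1 = regress(moving, fixed, self.CFG)
        r2 = regress(moving, fixed, self.CFG)
        np.testing.assert_array_equal(r1.loss_trace, r2.loss_trace)
        np.testing.assert_array_equal(r1.H_final.matrix, r2.H_final.matrix)

    def test_greyscale_inputs_supported(self, texture64):
        grey = texture64 @ np.array([0.299, 0.587, 0.114])
        res = regress(grey, grey, self.CFG)
        assert corner_error(res.H_final, Homography.identity(), 64) < 0.5

    def test_mixed_formats_rejected(self, texture64):
        grey = texture64[:, :, 0]
        with pytest.raises(ValueError):
            regress(texture64, grey, self.CFG)


class TestBlend:
    def test_zero_first_image_gives_pure_magenta(self, rng):
        b = rng.random((8, 8))
        out = blend(np.zeros((8, 8)), b, mode="greyscale")
        np.testing.assert_array_equal(out[:, :, 0], b)
        np.testing.assert_array_equal(out[:, :, 2], b)
        assert not out[:, :, 1].any()

    def test_identical_inputs_blend_to_neutral_grey(self, rng):
        a = rng.random((8, 8))
        out = blend(a, a, mode="greyscale")
        np.testing.assert_array_equal(out[:, :, 0], out[:, :, 1])
        np.testing.assert_array_equal(out[:, :, 1], out[:, :, 2])

    def test_colour_alpha_one_returns_first(self, texture64):
        other = np.zeros_like(texture64)
        np.testing.assert_array_equal(blend(texture64, other, mode="colour", alpha=1.0), texture64)

    def test_shape_mismatch_rejected(self, texture64):
        with pytest.raises(ValueError):
            blend(texture64, texture64[:32], mode="greyscale")
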