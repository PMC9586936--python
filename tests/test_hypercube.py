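"""Hypercube denoising, lifetime reconstruction and photon filtering."""

import numpy as np
import pytest

from flimcoreg.hypercube import (
    FlimHypercube,
    SpectralStack,
    spectral_moving_mean,
    reconstruct,
    photon_filter,
    global_normalise,
    save_hypercube,
    load_hypercube,
    save_stack,
    load_stack,
)
from flimcoreg.synthetic import poisson_decay

from conftest import make_cube


class TestMovingMean:
    def test_spectrally_constant_cube_is_unchanged(self, rng):
        plane = rng.poisson(50, (8, 8, 1, 6)).astype(float)
        cube = make_cube(np.repeat(plane, 12, axis=2))
        out = spectral_moving_mean(cube, 8)
        np.testing.assert_allclose(out.counts, cube.counts)

    def test_width_one_is_identity(self, rng):
        cube = make_cube(rng.poisson(20, (6, 6, 10, 5)))
        out = spectral_moving_mean(cube, 1)
        np.testing.assert_array_equal(out.counts, cube.counts)

    def test_interior_variance_reduced_by_window_size(self, rng):
        # i.i.d. noise: averaging 8 bands cuts the variance ~8-fold
        cube = make_cube(rng.normal(100, 10, (32, 32, 64, 4)).clip(min=0))
        out = spectral_moving_mean(cube, 8)
        v_in = cube.counts[:, :, 8:-8].std()
        v_out = out.counts[:, :, 8:-8].std()
        ratio = (v_in / v_out) ** 2
        assert 8 * 0.8 < ratio < 8 * 1.2

    def test_matches_truncated_window_oracle(self, rng):
        cube = make_cube(rng.poisson(30, (4, 4, 9, 3)))
        out = spectral_moving_mean(cube, 4)
        S = 9
        for s in range(S):
            lo, hi = max(0, s - 1), min(S - 1, s + 2)
            np.testing.assert_allclose(
                out.counts[:, :, s], cube.counts[:, :, lo : hi + 1].mean(axis=2)
            )

    @pytest.mark.parametrize("width", [0, -1, 11])
    def test_invalid_width_rejected(self, rng, width):
        cube = make_cube(rng.poisson(5, (4, 4, 10, 3)))
        with pytest.raises(ValueError):
            spectral_moving_mean(cube, width)

    def test_conserves_interior_photon_totals(self, rng):
        # with empty edge bands every photon stays within the spectral axis
        counts = np.zeros((8, 8, 20, 4))
        counts[:, :, 8:12] = rng.poisson(40, (8, 8, 4, 4))
        cube = make_cube(counts)
        out = spectral_moving_mean(cube, 8)
        np.testing.assert_allclose(out.counts.sum(), cube.counts.sum(), rtol=1e-10)


class TestReconstruct:
    def test_noiseless_decay_fit_is_exact(self):
        t = (np.arange(32) + 0.5) * 0.4
        for tau in [0.5, 2.0, 5.0]:
            decay = 1000 * np.exp(-t / tau)
            cube = make_cube(np.tile(decay, (2, 2, 3, 1)))
            stack = reconstruct(cube)
            np.testing.assert_allclose(stack.lifetime, tau, rtol=1e-6)

    def test_intensity_is_exact_time_sum(self, rng):
        cube = make_cube(rng.poisson(10, (6, 6, 3, 12)))
        stack = reconstruct(cube)
        np.testing.assert_array_equal(stack.intensity, cube.counts.sum(axis=3))

    def test_poisson_recovery_within_five_percent_rms(self):
        tau, n_pix = 2.5, 100
        rng = np.random.default_rng(3)
        counts = np.stack(
            [poisson_decay(tau, 1e4, 32, 0.4, rng) for _ in range(n_pix)]
        ).reshape(10, 10, 1, 32)
        stack = reconstruct(make_cube(counts))
        rms = np.sqrt(np.mean((stack.lifetime - tau) ** 2)) / tau
        assert rms < 0.05

    def test_all_zero_cube_gives_zero_stack(self):
        stack = reconstruct(make_cube(np.zeros((4, 4, 2, 8))))
        assert not stack.intensity.any()
        assert not stack.lifetime.any()

    def test_non_finite_counts_rejected(self):
        counts = np.zeros((4, 4, 2, 8))
        counts[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            make_cube(counts)

    def test_low_count_pixels_get_zero_lifetime(self):
        t = (np.arange(8) + 0.5) * 0.4
        counts = np.tile(2 * np.exp(-t / 2.0), (4, 4, 1, 1))  # ~10 counts total
        stack = reconstruct(make_cube(counts), fit_floor=25)
        assert not stack.lifetime.any()

    def test_too_few_time_channels_rejected(self):
        with pytest.raises(ValueError):
            reconstruct(make_cube(np.ones((4, 4, 2, 2))))


class TestPhotonFilter:
    def test_matches_elementwise_oracle(self, rng):
        stack = SpectralStack(
            intensity=rng.poisson(100, (8, 8, 3)).astype(float),
            lifetime=rng.uniform(0.5, 4.0, (8, 8, 3)),
            wavelengths=[500, 600, 700],
        )
        out = photon_filter(stack, scope="band")
        nhat = stack.intensity.mean(axis=(0, 1))
        for x in range(8):
            for y in range(8):
                for s in range(3):
                    if stack.intensity[x, y, s] <= np.sqrt(nhat[s]):
                        assert out.intensity[x, y, s] == 0
                        assert out.lifetime[x, y, s] == 0
                    else:
                        assert out.intensity[x, y, s] == stack.intensity[x, y, s]
                        assert out.lifetime[x, y, s] == stack.lifetime[x, y, s]

    def test_boundary_equality_is_zeroed(self):
        # Nhat frozen at 100: a pixel exactly at sqrt(Nhat)=10 is removed,
        # one photon above passes untouched
        inten = np.array([[[10.0], [11.0]]])
        life = np.array([[[1.7], [2.1]]])
        stack = SpectralStack(intensity=inten, lifetime=life, wavelengths=[550])
        out = photon_filter(stack, nhat=100.0)
        assert out.intensity[0, 0, 0] == 0 and out.lifetime[0, 0, 0] == 0
        assert out.intensity[0, 1, 0] == 11.0 and out.lifetime[0, 1, 0] == 2.1

    def test_idempotent_with_frozen_nhat(self, rng):
        stack = SpectralStack(
            intensity=rng.poisson(50, (6, 6, 2)).astype(float),
            lifetime=rng.uniform(1, 3, (6, 6, 2)),
            wavelengths=[500, 600],
        )
        once = photon_filter(stack, nhat=50.0)
        twice = photon_filter(once, nhat=50.0)
        np.testing.assert_array_equal(once.intensity, twice.intensity)
        np.testing.assert_array_equal(once.lifetime, twice.lifetime)

    def test_no_lifetime_without_intensity(self, rng):
        cube = make_cube(rng.poisson(3, (8, 8, 2, 16)))
        out = photon_filter(reconstruct(cube))
        assert not np.any((out.lifetime > 0) & (out.intensity == 0))

    def test_all_zero_input_is_legal(self):
        stack = SpectralStack(
            intensity=np.zeros((4, 4, 2)), lifetime=np.zeros((4, 4, 2)), wavelengths=[500, 600]
        )
        out = photon_filter(stack)
        assert not out.intensity.any()


class TestGlobalNormalise:
    def _stack(self, peak, rng):
        inten = rng.uniform(0, peak, (6, 6, 2))
        inten.flat[0] = peak
        return SpectralStack(
            intensity=inten, lifetime=rng.uniform(1, 3, (6, 6, 2)), wavelengths=[500, 600]
        )

    def test_single_stack_max_becomes_one(self, rng):
        out, = global_normalise([self._stack(500.0, rng)])
        assert out.intensity.max() == pytest.approx(1.0)

    def test_shared_factor_across_stacks(self, rng):
        s1, s2 = self._stack(500.0, rng), self._stack(1000.0, rng)
        o1, o2 = global_normalise([s1, s2])
        assert o2.intensity.max() == pytest.approx(1.0)
        assert o1.intensity.max() == pytest.approx(0.5)

    def test_ordering_preserved_and_lifetime_untouched(self, rng):
        s = self._stack(700.0, rng)
        o, = global_normalise([s])
        assert np.array_equal(np.argsort(s.intensity.ravel()), np.argsort(o.intensity.ravel()))
        np.testing.assert_array_equal(o.lifetime, s.lifetime)

    def test_all_zero_collection_warns_and_passes_through(self):
        s = SpectralStack(
            intensity=np.zeros((4, 4, 1)), lifetime=np.zeros((4, 4, 1)), wavelengths=[500]
        )
        with pytest.warns(RuntimeWarning):
            out, = global_normalise([s])
        assert not out.intensity.any()


def test_hdf5_round_trip(tmp_path, rng):
    cube = make_cube(rng.poisson(20, (8, 8, 4, 8)))
    save_hypercube(tmp_path / "c.h5", cube)
    back = load_hypercube(tmp_path / "c.h5")
    np.testing.assert_array_equal(back.counts, cube.counts)
    np.testing.assert_allclose(back.wavelengths, cube.wavelengths)
    stack = photon_filter(reconstruct(cube))
    save_stack(tmp_path / "s.h5", stack)
    back = load_stack(tmp_path / "s.h5")
    np.testing.assert_array_equal(back.lifetime, stack.lifetime)
    np.testing.assert_array_equal(back.intensity, stack.intensity)
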