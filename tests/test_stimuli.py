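"""Stimulus module: filters, synthetic ensembles, ON/OFF encoding, gratings."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from lgnv1.stimuli import (
    CONTRAST_GRID,
    ORIENTATION_GRID,
    FilterSpec,
    GratingSpec,
    apply_zero_phase_filter,
    build_filter,
    encode_on_off,
    generate_grating,
    generate_pink_noise_ensemble,
    make_whitened_ensemble,
    radial_frequency_grid,
    sample_patches,
)


class TestBuildFilter:
    def test_whitening_amplitude_at_cutoff(self):
        # R(f_c) = f_c * e^-1; with f_c = 200 that is ~73.58
        spec = FilterSpec("whitening", cutoff=200.0, image_size=512)
        H = build_filter(spec)
        f = radial_frequency_grid(512)
        # pick a bin with radial frequency exactly 200 (fx=200, fy=0)
        i = np.argmin(np.abs(np.fft.fftfreq(512) * 512 - 200.0))
        assert f[0, i] == pytest.approx(200.0)
        assert H[0, i] == pytest.approx(200.0 * np.exp(-1.0), rel=1e-12)

    def test_dc_bins(self):
        assert build_filter(FilterSpec("whitening", 200.0, 512), 32)[0, 0] == 0.0
        assert build_filter(FilterSpec("lowpass", 200.0, 512), 32)[0, 0] == 1.0

    def test_cutoff_rescales_with_size(self):
        # 200 cycles/image at 512 px is 6.25 cycles/patch at 16 px, so the
        # amplitude maximum of R(f) = f exp(-(f/fc)^4) sits at the same
        # cycles-per-pixel position in both builds.
        spec = FilterSpec("whitening", 200.0, 512)
        H16 = build_filter(spec, 16)
        H512 = build_filter(spec, 512)
        # at f' = 6 cycles/patch the response follows the rescaled cutoff
        assert H16[0, 6] == pytest.approx(6.0 * np.exp(-((6.0 / 6.25) ** 4)), rel=1e-12)
        # same cycles-per-pixel (6/16 = 192/512): responses match up to the
        # linear frequency factor 32 of the whitening filter
        assert H512[0, 192] == pytest.approx(32.0 * H16[0, 6], rel=1e-12)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            FilterSpec("whitening", cutoff=-1.0)
        with pytest.raises(ValueError):
            FilterSpec("bandpass", cutoff=10.0)


class TestZeroPhaseFilter:
    def test_identity_filter_is_noop(self):
        rng = np.random.default_rng(0)
        img = rng.standard_normal((1, 32, 32))
        out = apply_zero_phase_filter(img, np.ones((32, 32)))
        np.testing.assert_allclose(out, img, atol=1e-12)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        img = rng.standard_normal((32, 32))
        H = build_filter(FilterSpec("whitening", 200.0, 512), 32)
        np.testing.assert_allclose(
            apply_zero_phase_filter(3.5 * img, H),
            3.5 * apply_zero_phase_filter(img, H),
            atol=1e-12,
        )

    def test_size_mismatch_raises(self):
        with pytest.raises(ValueError, match="size"):
            apply_zero_phase_filter(np.zeros((16, 16)), np.ones((32, 32)))

    def test_white_noise_output_spectrum(self):
        # filtering white noise by R(f) gives expected power spectrum
        # proportional to f^2 exp(-2 (f/fc)^4); check the radially
        # averaged periodogram against the analytic curve.
        rng = np.random.default_rng(2)
        size = 64
        spec = FilterSpec("whitening", 200.0, 512)
        H = build_filter(spec, size)
        imgs = rng.standard_normal((200, size, size))
        out = apply_zero_phase_filter(imgs, H)
        power = np.abs(np.fft.fft2(out, axes=(-2, -1))) ** 2
        mean_power = power.mean(axis=0)
        f = radial_frequency_grid(size)
        sel = (f > 1) & (f < size / 2 - 2)
        expected = size**2 * H**2  # E|FFT(white)|^2 = size^2
        ratio = mean_power[sel] / expected[sel]
        assert abs(np.mean(ratio) - 1.0) < 0.05

    def test_pink_noise_whitens_flat(self):
        # 1/f amplitude x f gain = flat spectrum below the cutoff
        ens = generate_pink_noise_ensemble(50, 64, seed=3)
        H = build_filter(FilterSpec("whitening", 200.0, 512), 64)
        out = apply_zero_phase_filter(ens.images, H)
        power = (np.abs(np.fft.fft2(out, axes=(-2, -1))) ** 2).mean(axis=0)
        f = radial_frequency_grid(64)
        # stay clearly below the (rescaled) cutoff of 25 cycles/image,
        # where the R(f) envelope is still essentially 1
        lo = power[(f > 2) & (f < 6)].mean()
        hi = power[(f > 8) & (f < 12)].mean()
        assert abs(np.log10(lo / hi)) < 0.1


class TestPinkNoiseEnsemble:
    def test_seeded_determinism(self):
        a = generate_pink_noise_ensemble(3, 32, seed=7)
        b = generate_pink_noise_ensemble(3, 32, seed=7)
        np.testing.assert_array_equal(a.images, b.images)

    def test_amplitude_slope_is_minus_one(self):
        ens = generate_pink_noise_ensemble(100, 64, seed=11)
        amp = np.abs(np.fft.fft2(ens.images, axes=(-2, -1))).mean(axis=0)
        f = radial_frequency_grid(64)
        sel = (f > 1.5) & (f < 24)
        slope = np.polyfit(np.log(f[sel]), np.log(amp[sel]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.1)

    def test_whitened_ensemble_variance(self):
        ens = make_whitened_ensemble(4, 128, seed=5)
        assert ens.variance() == pytest.approx(0.2, rel=0.01)
        assert ens.variance_target == 0.2

    def test_whitening_annihilates_dc(self):
        ens = make_whitened_ensemble(4, 64, seed=6)
        assert np.abs(ens.images.mean(axis=(1, 2))).max() < 1e-10


class TestLoadImageEnsemble:
    def test_npy_and_png_round_trip(self, tmp_path):
        from PIL import Image

        from lgnv1.stimuli import load_image_ensemble

        rng = np.random.default_rng(0)
        stack = rng.standard_normal((2, 16, 16))
        np.save(tmp_path / "imgs.npy", stack)
        ens = load_image_ensemble(tmp_path / "imgs.npy")
        np.testing.assert_array_equal(ens.images, stack)

        gray = (rng.random((16, 16)) * 255).astype(np.uint8)
        Image.fromarray(gray, mode="L").save(tmp_path / "img.png")
        ens2 = load_image_ensemble([tmp_path / "img.png"], variance_target=0.2)
        assert ens2.images.shape == (1, 16, 16)
        assert ens2.variance() == pytest.approx(0.2)


class TestSamplePatches:
    def test_shapes_and_determinism(self):
        ens = generate_pink_noise_ensemble(3, 32, seed=0)
        a = sample_patches(ens, 100, 16, rng=9)
        b = sample_patches(ens, 100, 16, rng=9)
        assert a.shape == (100, 16, 16)
        np.testing.assert_array_equal(a, b)

    def test_patch_equals_image_when_sizes_match(self):
        ens = generate_pink_noise_ensemble(1, 16, seed=0)
        patch = sample_patches(ens, 1, 16, rng=0)[0]
        np.testing.assert_array_equal(patch, ens.images[0])

    def test_oversized_patch_raises(self):
        ens = generate_pink_noise_ensemble(1, 16, seed=0)
        with pytest.raises(ValueError):
            sample_patches(ens, 1, 32, rng=0)


class TestOnOffEncoding:
    @pytest.mark.parametrize(
        "value, on, off", [(0.3, 0.3, 0.0), (-0.3, 0.0, 0.3), (0.0, 0.0, 0.0)]
    )
    def test_single_pixel_rule(self, value, on, off):
        patch = np.zeros((4, 4))
        patch[1, 2] = value
        stim = encode_on_off(patch)
        i = 1 * 4 + 2  # row-major flattening
        assert stim.x_on[i] == on
        assert stim.x_off[i] == off

    def test_zero_patch_gives_zero_vector(self):
        stim = encode_on_off(np.zeros((16, 16)))
        assert stim.x.shape == (512,)
        assert not stim.x.any()

    @given(
        arrays(
            float, (6, 6),
            elements=st.floats(-10, 10, allow_nan=False, width=32),
        )
    )
    def test_complementarity_and_reconstruction(self, patch):
        stim = encode_on_off(patch)
        assert (stim.x_on >= 0).all() and (stim.x_off >= 0).all()
        # each pixel drives at most one channel
        assert np.all(stim.x_on * stim.x_off == 0)
        np.testing.assert_allclose(stim.to_patch(), patch, atol=0)


class TestGratings:
    def test_zero_contrast_is_blank(self):
        g = generate_grating(GratingSpec(5, 0.1, 30.0, contrast=0.0))
        assert not g.any()

    def test_zero_outside_aperture(self):
        g = generate_grating(GratingSpec(3, 0.2, 0.0, contrast=1.0))
        rows, cols = np.meshgrid(np.arange(16), np.arange(16), indexing="ij")
        outside = np.hypot(cols - 7.5, rows - 7.5) > 3
        assert not g[outside].any()
        assert np.abs(g[~outside]).max() <= 1.0

    def test_oversized_radius_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamp"):
            g = generate_grating(GratingSpec(12, 0.1, 0.0))
        assert g.shape == (16, 16)

    def test_search_grids(self):
        assert len(ORIENTATION_GRID) == 36
        assert ORIENTATION_GRID[1] - ORIENTATION_GRID[0] == 5.0
        np.testing.assert_allclose(CONTRAST_GRID, [0.2, 0.4, 0.6, 0.8, 1.0])

    def test_orientation_convention(self):
        # a 0-degree grating varies along x (columns) and is constant in y
        g = generate_grating(GratingSpec(8, 0.25, 0.0, contrast=1.0))
        inner = g[6:10, 6:10]
        assert np.allclose(inner, inner[0:1, :], atol=1e-12)
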