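import numpy as np
import pytest

from scanstorm.psf import airy_psf
from scanstorm.wavelet import (FilterBank, gram_schmidt_couple, decompose,
                               reconstruct, detect_peaks, crop_rois,
                               train_wavelet_denoiser, denoise_frame,
                               robust_threshold, PeakList)


class TestCoupling:
    def test_already_orthogonal_unchanged(self):
        hp, lp = gram_schmidt_couple([1.0, 0.0], [0.0, 1.0])
        assert np.allclose(lp, [0.0, 1.0])

    def test_projection_subtracted(self):
        hp, lp = gram_schmidt_couple([1.0, 0.0], [1.0, 1.0])
        assert np.allclose(lp, [0.0, 1.0])

    def test_orthogonality_over_random_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            hp = rng.normal(0, 1, 2)
            lp = rng.normal(0, 1, 2)
            hpn, lpn = gram_schmidt_couple(hp, lp)
            assert abs(hpn @ lpn) < 1e-10

    def test_degenerate_high_pass_rejected(self):
        with pytest.raises(ValueError):
            gram_schmidt_couple([0.0, 0.0], [1.0, 1.0])


class TestTransform:
    def test_zero_image_zero_subbands(self):
        bank = FilterBank()
        ll, det = decompose(np.zeros((8, 8)), bank, activation=True)
        assert not ll.data.any()
        assert not any(b.data.any() for lev in det for b in lev)

    def test_haar_matches_reference_library(self):
        pywt = pytest.importorskip("pywt")
        rng = np.random.default_rng(0)
        img = np.abs(rng.normal(0, 1, (8, 8)))
        bank = FilterBank(levels=1)
        ll, det = decompose(img, bank, activation=False)
        cA, (cH, cV, cD) = pywt.dwt2(img, "haar")
        assert np.allclose(ll.data[0, 0], cA, atol=1e-12)
        assert np.allclose(det[0][0].data[0, 0], cH, atol=1e-12)
        assert np.allclose(det[0][1].data[0, 0], cV, atol=1e-12)
        assert np.allclose(det[0][2].data[0, 0], cD, atol=1e-12)

    def test_constant_image_has_zero_detail(self):
        bank = FilterBank()
        ll, det = decompose(np.full((8, 8), 3.7), bank, activation=False)
        for lev in det:
            for band in lev:
                assert np.allclose(band.data, 0.0, atol=1e-12)

    def test_perfect_reconstruction_random_taps(self):
        """reconstruct(decompose(x)) == x for any coupled taps, bias 0."""
        rng = np.random.default_rng(42)
        for i in range(100):
            bank = FilterBank(rng=np.random.default_rng(i))
            x = np.abs(rng.normal(0, 1, (16, 16)))
            ll, det = decompose(x, bank, activation=False)
            rec = reconstruct(ll, det, bank).data[0, 0]
            assert np.abs(rec - x).max() < 1e-6

    def test_zero_subbands_zero_image(self):
        bank = FilterBank()
        x = np.abs(np.random.default_rng(0).normal(0, 1, (8, 8)))
        ll, det = decompose(x, bank, activation=False)
        from scanstorm.nn import Tensor
        zero_ll = Tensor(np.zeros_like(ll.data))
        zero_det = [tuple(Tensor(np.zeros_like(b.data)) for b in lev)
                    for lev in det]
        assert not reconstruct(zero_ll, zero_det, bank).data.any()

    def test_thresholding_reduces_noise_variance(self):
        rng = np.random.default_rng(1)
        noise = rng.normal(0, 1, (32, 32))
        bank = FilterBank()
        ll, det = decompose(noise, bank, activation=False)
        zeroed = [tuple(b * 0.0 for b in lev) for lev in det]
        rec = reconstruct(ll, zeroed, bank).data[0, 0]
        assert rec.var() < noise.var()

    def test_indivisible_size_rejected(self):
        with pytest.raises(ValueError):
            decompose(np.zeros((9, 9)), FilterBank())


class TestPeaks:
    def test_constant_image_no_peaks(self):
        assert detect_peaks(np.full((20, 20), 2.0), 0.5).peaks == []

    def test_single_psf_single_peak(self):
        k = airy_psf(30, 121)
        img = np.zeros((45, 45))
        img[20 - 6:20 + 7, 17 - 6:17 + 7] = 1000 * k[60 - 6:60 + 7, 60 - 6:60 + 7]
        pl = detect_peaks(img, 0.01)
        assert pl.peaks == [(0, 20, 17)]

    def test_two_separated_psfs_two_peaks(self):
        k = airy_psf(30, 121)
        patch = 1000 * k[60 - 4:60 + 5, 60 - 4:60 + 5]
        img = np.zeros((45, 45))
        img[10 - 4:10 + 5, 10 - 4:10 + 5] += patch
        img[10 - 4:10 + 5, 20 - 4:20 + 5] += patch
        pl = detect_peaks(img, 0.01)
        assert sorted(pl.peaks) == [(0, 10, 10), (0, 10, 20)]

    def test_translation_equivariance(self):
        rng = np.random.default_rng(5)
        img = np.zeros((40, 40))
        img[12, 9] = 5.0
        img[25, 30] = 7.0
        base = detect_peaks(img, 1.0).peaks
        shifted = detect_peaks(np.roll(np.roll(img, 3, 0), 2, 1), 1.0).peaks
        assert sorted((f, r + 3, c + 2) for f, r, c in base) == sorted(shifted)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            detect_peaks(np.zeros((5, 5)), -1.0)


class TestCrops:
    def test_center_and_padding_contracts(self):
        rng = np.random.default_rng(2)
        frames = rng.normal(100, 10, (4, 9, 9))
        pl = PeakList(peaks=[(0, 4, 4)], scores=[1.0])
        crop = crop_rois(frames, pl)[0]
        assert crop.pixels.shape == (3, 9, 9)
        assert not crop.pixels[0].any()               # no previous frame
        assert np.allclose(crop.pixels[1], frames[0])
        assert crop.pixels[1][4][4] == frames[0, 4, 4]

    def test_corner_peak_zero_padded(self):
        frames = np.ones((3, 20, 20))
        crop = crop_rois(frames, PeakList(peaks=[(1, 0, 0)], scores=[1.0]))[0]
        assert crop.pixels.shape == (3, 9, 9)
        assert not crop.pixels[1, :4, :].any()
        assert not crop.pixels[1, :, :4].any()
        assert crop.pixels[1, 4:, 4:].all()
        assert crop.origin == (1, -4, -4)


class TestDenoiserTraining:
    def test_training_improves_heldout_mse(self, noisy_crops):
        train, held = noisy_crops[:40], noisy_crops[40:]
        bank, losses = train_wavelet_denoiser(train, epochs=40, rng=0)
        assert losses[-1] < losses[0]
        raw_mse, den_mse = [], []
        for c in held:
            den = denoise_frame(c.pixels[1], bank)
            raw_mse.append(((c.pixels[1] - c.noiseless) ** 2).mean())
            den_mse.append(((den - c.noiseless) ** 2).mean())
        assert np.mean(den_mse) < np.mean(raw_mse)

    def test_orthogonality_maintained_during_training(self, noisy_crops):
        bank = FilterBank()
        for _ in range(3):
            bank, _ = train_wavelet_denoiser(noisy_crops[:20], epochs=1,
                                             bank=bank, rng=1)
            hpn, lpn = bank.coupled()
            assert abs(float((hpn * lpn).sum().data)) < 1e-6

    def test_denoising_keeps_psf_maximum_close(self, clean_single_crops):
        """On noise-free input the denoised maximum stays within 1 pixel
        of the raw maximum."""
        bank = FilterBank()
        for c in clean_single_crops[:10]:
            img = c.noiseless
            if img.max() <= 0:
                continue
            den = denoise_frame(img, bank)
            r0, c0 = np.unravel_index(np.argmax(img), img.shape)
            r1, c1 = np.unravel_index(np.argmax(den), den.shape)
            assert abs(r1 - r0) <= 1 and abs(c1 - c0) <= 1
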