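import math

import numpy as np
import pytest

from giqe.blur import BlurSpec, apply_motion_blur, make_motion_psf
from giqe.features import (
    FeatureConfig,
    compute_maps,
    extract_features,
    features_from_maps,
    lgf_feature,
    lsf_feature,
    mif_feature,
    nsf_feature,
    phase_congruency_map,
    scharr_gradient_map,
    vsf_feature,
)
from giqe.loggabor import LogGaborBank, log_gabor_transfer, phase_congruency
from giqe.saliency import saliency_map

from oracles import (
    information_oracle,
    lgf_oracle,
    lsf_oracle,
    nsf_oracle,
    scharr_center,
    vsf_oracle,
)

CFG = FeatureConfig()


def _toy_pair(rng, shape=(8, 8), channels=None):
    size = shape if channels is None else (*shape, channels)
    ref = rng.uniform(0, 255, size)
    dist = np.clip(ref + rng.normal(0, 20, size), 0, 255)
    return ref, dist


class TestLogGabor:
    def test_transfer_peaks_at_one_and_zero_dc(self):
        v = log_gabor_transfer(np.array([1 / 6]), np.array([0.8]), 1 / 6, 0.55, 0.8, 0.52)
        assert v[0] == pytest.approx(1.0)
        assert log_gabor_transfer(np.array([0.0]), np.array([0.0]), 1 / 6, 0.55, 0.0, 0.52)[0] == 0.0

    def test_bank_rejects_super_nyquist_frequencies(self):
        with pytest.raises(ValueError, match="Nyquist"):
            LogGaborBank(center_freqs=(0.7,))

    def test_image_smaller_than_wavelength_rejected(self):
        bank = LogGaborBank.octave(3, 4, min_wavelength=16)
        with pytest.raises(ValueError, match="wavelength"):
            phase_congruency(np.zeros((8, 8)), bank)


class TestPhaseCongruency:
    def test_constant_image_has_no_phase_structure(self):
        pc = phase_congruency_map(np.full((32, 32), 80.0), CFG)
        assert pc.max() < 1e-6

    def test_bounded_unit_interval(self, rng):
        pc = phase_congruency_map(rng.uniform(0, 255, (32, 32)), CFG)
        assert pc.min() >= 0.0 and pc.max() <= 1.0 + 1e-12

    def test_step_edge_is_maximally_congruent(self):
        # DFT periodicity puts a second edge at the wrap column, so compare
        # the edge columns against the quarter-way (edge-free) columns.
        img = np.zeros((32, 32))
        img[:, 16:] = 200.0
        pc = phase_congruency(img, LogGaborBank.octave(2, 4))
        col_strength = pc[8:-8].mean(axis=0)
        edge = col_strength[[15, 16]].mean()
        off_edge = col_strength[[8, 24]].mean()
        assert edge > off_edge


class TestScharr:
    def test_constant_and_ramp(self):
        assert np.allclose(scharr_gradient_map(np.full((8, 8), 9.0)), 0.0)
        # unit ramp: the /16-normalized Scharr pair responds with 2 (the
        # [1,0,-1] differencing spans two pixels)
        ramp = np.tile(np.arange(8, dtype=float), (8, 1))
        interior = scharr_gradient_map(ramp)[1:-1, 1:-1]
        np.testing.assert_allclose(interior, 2.0, atol=1e-12)

    def test_center_pixel_matches_stencil_oracle(self, rng):
        img = rng.uniform(0, 255, (5, 5))
        assert scharr_gradient_map(img)[2, 2] == pytest.approx(scharr_center(img), abs=1e-10)


class TestSaliency:
    def test_constant_image_uniform(self):
        sal = saliency_map(np.full((64, 64), 42.0))
        assert np.ptp(sal) == 0.0

    def test_bright_blob_is_global_maximum(self):
        yy, xx = np.mgrid[0:96, 0:96]
        img = 20.0 + 200.0 * np.exp(-(((yy - 30) ** 2 + (xx - 60) ** 2) / (2 * 6.0 ** 2)))
        sal = saliency_map(img)
        r, c = np.unravel_index(np.argmax(sal), sal.shape)
        assert (r - 30) ** 2 + (c - 60) ** 2 < 20 ** 2

    def test_normalized_range(self, rng):
        sal = saliency_map(rng.uniform(0, 255, (64, 64, 3)))
        assert sal.min() >= 0.0 and sal.max() <= 1.0


class TestFeatureOracles:
    """Each feature must equal its literal-formula transcription on toys."""

    def test_lsf_matches_oracle(self, rng):
        ref, dist = _toy_pair(rng)
        pc_r, pc_d = phase_congruency_map(ref, CFG), phase_congruency_map(dist, CFG)
        gm_r, gm_d = scharr_gradient_map(ref), scharr_gradient_map(dist)
        expected = lsf_oracle(pc_r, pc_d, gm_r, gm_d, CFG.a_pc, CFG.a1, CFG.alpha, CFG.beta)
        assert lsf_feature(ref, dist, CFG) == pytest.approx(expected, abs=1e-6)

    def test_vsf_matches_oracle(self, rng):
        ref, dist = _toy_pair(rng, channels=3)
        from giqe.features import _CHROMA_M, _CHROMA_N

        expected = vsf_oracle(
            saliency_map(ref), saliency_map(dist),
            scharr_gradient_map(ref), scharr_gradient_map(dist),
            ref @ _CHROMA_M, dist @ _CHROMA_M,
            ref @ _CHROMA_N, dist @ _CHROMA_N,
            CFG.a1, CFG.a2, CFG.alpha, CFG.beta,
        )
        assert vsf_feature(ref, dist, CFG) == pytest.approx(expected, abs=1e-6)

    def test_lgf_matches_dft_oracle(self, rng):
        ref, dist = _toy_pair(rng, shape=(16, 16))
        bank = LogGaborBank(center_freqs=(1 / 6,), orientations=(math.pi / 4,))
        cfg = FeatureConfig(lgf_bank=bank)
        expected = lgf_oracle(ref, dist, 1 / 6, bank.bandwidth_ratio,
                              math.pi / 4, bank.angular_spread, cfg.a1)
        assert lgf_feature(ref, dist, cfg) == pytest.approx(expected, abs=1e-6)

    def test_mif_matches_log_determinant_oracle(self, rng):
        ref, dist = _toy_pair(rng)
        cfg = FeatureConfig(block_size=2)
        info_r = information_oracle(ref, 2, cfg.mif_noise_var)
        info_d = information_oracle(dist, 2, cfg.mif_noise_var)
        expected = min(info_d / info_r, 1.0)
        assert mif_feature(ref, dist, cfg) == pytest.approx(expected, abs=1e-6)

    def test_nsf_matches_block_oracle(self, rng):
        ref, dist = _toy_pair(rng)
        expected = nsf_oracle(scharr_gradient_map(ref), scharr_gradient_map(dist), 4, CFG.a3)
        assert nsf_feature(ref, dist, CFG) == pytest.approx(expected, abs=1e-6)


class TestFeatureContracts:
    def test_identity_pair_scores_one(self, rng):
        img = rng.uniform(0, 255, (32, 32, 3))
        fv = extract_features(img, img, CFG)
        np.testing.assert_allclose(fv.to_array(), 1.0, atol=1e-9)

    def test_vector_composes_individual_features(self, rng):
        ref, dist = _toy_pair(rng, shape=(32, 32), channels=3)
        fv = extract_features(ref, dist, CFG)
        assert fv.f_lsf == pytest.approx(lsf_feature(ref, dist, CFG), abs=1e-12)
        assert fv.f_vsf == pytest.approx(vsf_feature(ref, dist, CFG), abs=1e-12)
        assert fv.f_lgf == pytest.approx(lgf_feature(ref, dist, CFG), abs=1e-12)
        assert fv.f_mif == pytest.approx(mif_feature(ref, dist, CFG), abs=1e-12)
        assert fv.f_nsf == pytest.approx(nsf_feature(ref, dist, CFG), abs=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            extract_features(rng.uniform(0, 255, (16, 16)), rng.uniform(0, 255, (16, 17)))

    def test_grayscale_pair_uses_unit_chrominance(self, rng):
        ref, dist = _toy_pair(rng, shape=(16, 16))
        got = vsf_feature(ref, dist, CFG)
        s_vs = np.mean(
            (2 * 255 * saliency_map(ref) * 255 * saliency_map(dist) + CFG.a2)
            / ((255 * saliency_map(ref)) ** 2 + (255 * saliency_map(dist)) ** 2 + CFG.a2)
        )
        gm_r, gm_d = scharr_gradient_map(ref), scharr_gradient_map(dist)
        s_gm = np.mean((2 * gm_r * gm_d + CFG.a1) / (gm_r ** 2 + gm_d ** 2 + CFG.a1))
        assert got == pytest.approx(float(s_vs) * float(s_gm) ** CFG.alpha, rel=1e-9)

    def test_blur_degrades_each_feature(self, textured_rgb):
        """Mild vs severe blur: every feature is lower at L=25 than at L=5."""
        cfg = FeatureConfig()
        ref_maps = compute_maps(textured_rgb, cfg)
        vals = {}
        for L in (5, 25):
            blurred = apply_motion_blur(textured_rgb, make_motion_psf(BlurSpec(L, 60)))
            vals[L] = features_from_maps(ref_maps, compute_maps(blurred, cfg), cfg).to_array()
        assert np.all(vals[25] < vals[5])

    def test_features_bounded_on_blurred_pair(self, textured_rgb):
        blurred = apply_motion_blur(textured_rgb, make_motion_psf(BlurSpec(15, 30)))
        fv = extract_features(textured_rgb, blurred, CFG).to_array()
        assert np.all(fv > 0.0) and np.all(fv <= 1.0)
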