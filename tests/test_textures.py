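"""Texture features: worked examples, brute-force oracles, invariants."""

import numpy as np
import pytest
from skimage.feature import graycomatrix

from conftest import random_roi, split_xy
from geltexture import textures
from geltexture.textures import (
    GLCM_OFFSETS,
    GLCMOffset,
    ar_features,
    default_inventory,
    extract_all,
    glcm,
    glcm_features,
    gradient_features,
    histogram_features,
    quantize,
    rlm_features,
    wavelet_features,
)
import oracles


def const_roi(value=100, size=8):
    return np.full((size, size), value, dtype=np.uint8)


class TestQuantize:
    @pytest.mark.parametrize("grey, level", [(255, 4), (0, 1), (64, 2)])
    def test_full_range_mapping(self, grey, level):
        q = quantize(const_roi(grey), ng=4)
        assert (q.levels == level).all()

    def test_quantization_is_monotone_in_grey_level(self, rng):
        pixels = rng.integers(0, 256, size=(12, 12)).astype(np.uint8)
        q = quantize(pixels, ng=16)
        flat_g = pixels.ravel().astype(int)
        flat_l = q.levels.ravel()
        order = np.argsort(flat_g)
        assert (np.diff(flat_l[order]) >= 0).all()

    def test_constant_roi_under_percentile_mode_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="full-range"):
            q = quantize(const_roi(100), ng=8, normalization="percentile-1-99")
        assert (q.levels == int(np.floor(100 * 8 / 256)) + 1).all()

    def test_bad_ng_rejected(self):
        with pytest.raises(ValueError):
            quantize(const_roi(), ng=1)


class TestHistogram:
    def test_constant_roi_degenerate_conventions(self):
        f = histogram_features(const_roi(37))
        assert f["Mean"] == 37
        assert f["Variance"] == f["Skewness"] == f["Kurtosis"] == 0
        assert all(f[f"Perc.{q:02d}%"] == 37 for q in (1, 10, 50, 90, 99))

    def test_two_value_population_moments(self):
        pixels = np.array([[100] * 8, [200] * 8], dtype=np.uint8)
        f = histogram_features(pixels)
        assert f["Mean"] == 150
        assert f["Variance"] == 2500
        assert f["Skewness"] == 0

    def test_percentiles_are_monotone(self, rng):
        for _ in range(10):
            pixels, mask = random_roi(rng)
            f = histogram_features(pixels)
            percs = [f[f"Perc.{q:02d}%"] for q in (1, 10, 50, 90, 99)]
            assert percs == sorted(percs)

    def test_matches_loop_oracle(self, rng):
        pixels, mask = random_roi(rng, full_mask=False)
        got = histogram_features(type("R", (), {"pixels": pixels, "mask": mask}))
        want = oracles.hist_oracle(pixels[mask].astype(float))
        for k, v in want.items():
            assert got[k] == pytest.approx(v, rel=1e-9)


class TestGradient:
    def test_constant_roi_all_zero(self):
        f = gradient_features(const_roi())
        assert all(v == 0 for v in f.values())

    def test_horizontal_ramp_magnitude_two_everywhere(self):
        pixels = np.tile(np.arange(5, dtype=np.uint8), (5, 1))
        f = gradient_features(pixels)
        assert f["GrMean"] == pytest.approx(2.0)
        assert f["GrVariance"] == 0
        assert f["GrNonZeros"] == 1.0

    def test_vertical_ramp_matches_horizontal_by_isotropy(self):
        h = gradient_features(np.tile(np.arange(5, dtype=np.uint8), (5, 1)))
        v = gradient_features(np.tile(np.arange(5, dtype=np.uint8), (5, 1)).T)
        assert h == v

    def test_too_small_roi_raises(self):
        with pytest.raises(ValueError, match="interior"):
            gradient_features(np.zeros((2, 2), dtype=np.uint8))


class TestGLCM:
    def test_constant_roi_all_mass_on_diagonal(self):
        q = quantize(const_roi(128), ng=8)
        p = glcm(q, GLCMOffset(1, 0))
        level = q.levels[0, 0] - 1
        assert p[level, level] == 1.0
        assert p.sum() == pytest.approx(1.0)

    def test_checkerboard_horizontal_offset(self):
        pixels = np.zeros((4, 4), dtype=np.uint8)
        pixels[::2, 1::2] = 255
        pixels[1::2, ::2] = 255
        q = quantize(pixels, ng=2)
        p = glcm(q, GLCMOffset(1, 0))
        assert p[0, 1] == pytest.approx(0.5)
        assert p[1, 0] == pytest.approx(0.5)
        assert p[0, 0] == p[1, 1] == 0

    def test_sums_to_one_for_every_offset_on_masked_rois(self, rng):
        for _ in range(5):
            pixels, mask = random_roi(rng, full_mask=False)
            q = quantize(type("R", (), {"pixels": pixels, "mask": mask}), ng=16)
            for off in GLCM_OFFSETS:
                assert abs(glcm(q, off).sum() - 1.0) < 1e-12

    def test_agrees_with_skimage_on_rectangular_rois(self, rng):
        """Independent library route: skimage's graycomatrix on full masks."""
        pixels, _ = random_roi(rng, size=20)
        q = quantize(pixels, ng=16)
        # axial offsets only: skimage rounds d*sin/cos(theta), so its diagonal
        # offsets at d >= 2 are not the integer steps (d, d) used here
        for off in [o for o in GLCM_OFFSETS if o.theta in (0, 90)]:
            ours = glcm(q, off)
            angle = np.deg2rad(off.theta)
            theirs = graycomatrix(
                (q.levels - 1).astype(np.uint8), [off.d], [angle],
                levels=16, symmetric=True, normed=True,
            )[:, :, 0, 0]
            np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_no_valid_pairs_raises_with_offset_named(self):
        pixels = np.full((3, 8), 100, dtype=np.uint8)
        mask = np.zeros((3, 8), dtype=bool)
        mask[:, 0] = True  # single column: no horizontal pairs at d=5
        with pytest.raises(ValueError, match="offset"):
            glcm(quantize(type("R", (), {"pixels": pixels, "mask": mask}), ng=4),
                 GLCMOffset(5, 0))


class TestGLCMFeatures:
    def test_diagonal_matrix_extremes(self):
        p = np.zeros((4, 4))
        p[2, 2] = 1.0
        f = glcm_features(p)
        assert f["InvDfMom"] == 1.0
        assert f["Contrast"] == 0.0
        assert f["AngScMom"] == 1.0
        assert f["Entropy"] == 0.0

    def test_checkerboard_matrix_values(self):
        p = np.array([[0.0, 0.5], [0.5, 0.0]])
        f = glcm_features(p)
        assert f["InvDfMom"] == pytest.approx(0.5)
        assert f["Contrast"] == pytest.approx(1.0)
        assert f["AngScMom"] == pytest.approx(0.5)

    def test_bounds_on_random_matrices(self, rng):
        for _ in range(20):
            raw = rng.random((6, 6))
            p = (raw + raw.T) / (raw + raw.T).sum()
            f = glcm_features(p)
            assert 0 < f["InvDfMom"] <= 1
            assert f["AngScMom"] <= 1


class TestRLM:
    def test_constant_4x4_horizontal_runs(self):
        q = quantize(const_roi(100, size=4), ng=8)
        f = rlm_features(q, "H")
        assert f["ShrtREmp_H"] == pytest.approx(0.0625)
        assert f["LngREmph_H"] == pytest.approx(16.0)
        assert f["GLevNonU_H"] == pytest.approx(4.0)
        assert f["RLNonUni_H"] == pytest.approx(4.0)
        assert f["Fraction_H"] == pytest.approx(0.25)

    def test_alternating_rows_all_unit_runs(self):
        pixels = np.tile(np.array([0, 255] * 4, dtype=np.uint8), (4, 1))
        q = quantize(pixels, ng=2)
        f = rlm_features(q, "H")
        assert f["ShrtREmp_H"] == 1.0
        assert f["LngREmph_H"] == 1.0
        assert f["Fraction_H"] == 1.0

    @pytest.mark.parametrize("direction", ["H", "V", "45", "135"])
    def test_fraction_in_unit_interval_and_oracle_agreement(self, rng, direction):
        pixels, mask = random_roi(rng, full_mask=False)
        q = quantize(type("R", (), {"pixels": pixels, "mask": mask}), ng=8)
        f = rlm_features(q, direction)
        assert 0 < f[f"Fraction_{direction}"] <= 1
        want = oracles.rlm_oracle(q.levels, mask, 8, direction)
        got = textures.run_length_matrix(q, direction)
        assert got[:, : want.shape[1]].sum() == want.sum()
        np.testing.assert_allclose(got[:, : want.shape[1]], want)


class TestAR:
    def test_constant_roi_degenerate_fit(self):
        f = ar_features(const_roi())
        assert f == {"Teta1": 0.0, "Teta2": 0.0, "Teta3": 0.0, "Teta4": 0.0,
                     "Sigma": 0.0}

    def test_left_neighbour_process_recovers_theta1(self, rng):
        # each pixel = its left neighbour plus a small innovation
        h, w = 24, 24
        pixels = np.zeros((h, w))
        pixels[:, 0] = rng.normal(128, 30, size=h)
        for c in range(1, w):
            pixels[:, c] = pixels[:, c - 1] + rng.normal(0, 1.0, size=h)
        pixels = np.clip(pixels, 0, 255).astype(np.uint8)
        f = ar_features(pixels)
        assert f["Teta1"] == pytest.approx(1.0, abs=0.15)
        assert abs(f["Teta2"]) < 0.3 and abs(f["Teta4"]) < 0.3
        assert f["Sigma"] < 5.0

    def test_matches_normal_equations_oracle(self, rng):
        pixels, mask = random_roi(rng, full_mask=False)
        got = ar_features(type("R", (), {"pixels": pixels, "mask": mask}))
        theta, sigma = oracles.ar_oracle(pixels, mask)
        for i in range(4):
            assert got[f"Teta{i+1}"] == pytest.approx(theta[i], rel=1e-8, abs=1e-8)
        assert got["Sigma"] == pytest.approx(sigma, rel=1e-8)

    def test_sigma_nonnegative_and_zero_only_for_exact_fit(self, rng):
        pixels, mask = random_roi(rng)
        f = ar_features(pixels)
        assert f["Sigma"] > 0  # random noise cannot be fit exactly


class TestWavelet:
    def test_constant_roi_has_no_detail_energy(self):
        f = wavelet_features(const_roi(200, size=16))
        for s in (1, 2, 3, 4):
            for band in ("LH", "HL", "HH"):
                assert f[f"WavEn{band}_s{s}"] == pytest.approx(0.0, abs=1e-20)

    def test_matches_explicit_haar_oracle_on_8x8(self, rng):
        pixels = rng.integers(0, 256, size=(8, 8)).astype(np.uint8)
        f = wavelet_features(pixels, scales=3)
        a = pixels.astype(float)
        for s in (1, 2, 3):
            ll, lh, hl, hh = oracles.haar2d_oracle(a)
            assert f[f"WavEnLL_s{s}"] == pytest.approx((ll ** 2).mean(), rel=1e-9)
            got_det = sorted(
                [f[f"WavEnLH_s{s}"], f[f"WavEnHL_s{s}"], f[f"WavEnHH_s{s}"]]
            )
            want_det = sorted([(lh ** 2).mean(), (hl ** 2).mean(), (hh ** 2).mean()])
            np.testing.assert_allclose(got_det, want_det, rtol=1e-9)
            a = ll

    def test_oriented_pattern_separates_lh_from_hl(self):
        # horizontal stripes: detail energy concentrated in one oriented band
        pixels = np.tile(np.array([[0], [255]], dtype=np.uint8), (8, 16))
        f = wavelet_features(pixels, scales=1)
        strong = max(f["WavEnLH_s1"], f["WavEnHL_s1"])
        weak = min(f["WavEnLH_s1"], f["WavEnHL_s1"])
        assert strong > 0 and weak == pytest.approx(0.0, abs=1e-20)

    def test_detail_energies_invariant_to_constant_shift(self, rng):
        pixels = rng.integers(0, 200, size=(16, 16)).astype(np.uint8)
        f1 = wavelet_features(pixels)
        f2 = wavelet_features(pixels + 50)
        for name, v in f1.items():
            if "LL" not in name:
                assert f2[name] == pytest.approx(v, rel=1e-9, abs=1e-12)

    def test_tiny_bounding_box_raises(self):
        with pytest.raises(ValueError, match="2x2"):
            wavelet_features(np.zeros((1, 5), dtype=np.uint8))


class TestExtractAll:
    def test_default_inventory_has_274_uniquely_named_features(self):
        inv = default_inventory()
        assert len(inv) == 274
        assert len(set(inv.names)) == 274
        from collections import Counter
        by_group = Counter(g for _, g in inv.entries)
        assert by_group == {
            "Histogram": 9, "Gradient": 5, "GLCM": 220,
            "RLM": 20, "ARModel": 5, "Wavelet": 15,
        }

    def test_extraction_is_deterministic(self, rng):
        pixels, mask = random_roi(rng, size=20)
        roi = type("R", (), {"pixels": pixels, "mask": mask})
        assert extract_all(roi) == extract_all(roi)

    def test_pixel_permutation_keeps_histogram_changes_glcm(self, rng):
        pixels, _ = random_roi(rng, size=16)
        perm = np.random.default_rng(1).permutation(pixels.ravel()).reshape(16, 16)
        f1 = extract_all(pixels)
        f2 = extract_all(perm)
        for name in ("Mean", "Variance", "Perc.50%"):
            assert f1[name] == f2[name]
        assert f1["S(1,0)InvDfMom"] != f2["S(1,0)InvDfMom"]

    def test_all_families_match_brute_force_oracles(self, rng):
        """Twenty random 16x16 ROIs, 1e-9 relative agreement per family."""
        for trial in range(20):
            pixels, mask = random_roi(rng, full_mask=(trial % 2 == 0))
            roi = type("R", (), {"pixels": pixels, "mask": mask})
            got = extract_all(roi)
            # histogram
            for k, v in oracles.hist_oracle(pixels[mask].astype(float)).items():
                assert got[k] == pytest.approx(v, rel=1e-9, abs=1e-9)
            # gradient
            mags = oracles.gradient_oracle(pixels, mask)
            assert got["GrMean"] == pytest.approx(mags.mean(), rel=1e-9)
            assert got["GrVariance"] == pytest.approx(mags.var(), rel=1e-9, abs=1e-9)
            # GLCM via loop oracle, one offset per direction
            q = quantize(roi, ng=64)
            for off in (GLCMOffset(1, 0), GLCMOffset(2, 90),
                        GLCMOffset(1, 45), GLCMOffset(3, 135)):
                p_oracle = oracles.glcm_oracle(q.levels, mask, 64, off.step)
                feats = oracles.haralick_oracle(p_oracle)
                for k, v in feats.items():
                    assert got[f"{off.name}{k}"] == pytest.approx(
                        v, rel=1e-9, abs=1e-9
                    ), (trial, off.name, k)
            # AR
            theta, sigma = oracles.ar_oracle(pixels, mask)
            for i in range(4):
                assert got[f"Teta{i+1}"] == pytest.approx(theta[i], abs=1e-8)
            assert got["Sigma"] == pytest.approx(sigma, rel=1e-8)

    def test_failure_names_the_roi(self):
        roi = type("R", (), {
            "pixels": np.zeros((2, 2), dtype=np.uint8),
            "mask": np.ones((2, 2), dtype=bool),
            "roi_id": 99,
        })
        with pytest.raises(ValueError, match="99"):
            extract_all(roi)


def test_idm_is_higher_in_noise_than_in_spots(strong_signal_table):
    """Local homogeneity (inverse difference moment) separates the classes:
    noise regions change gradually, spots impose steep grey-level ramps."""
    t = strong_signal_table
    assert len(t) >= 100
    spot = t.loc[t.label == 1, "S(4,0)InvDfMom"]
    noise = t.loc[t.label == 0, "S(4,0)InvDfMom"]
    assert noise.mean() > spot.mean()
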