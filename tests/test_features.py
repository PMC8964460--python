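"""Oracles for the five profile descriptors and their concatenation."""

import numpy as np
import pytest
import pywt
import scipy.fft

from memdsn.errors import ConfigurationError
from memdsn.features import (
    FeatureConfig,
    avblock_features,
    dct_features,
    dwt_features,
    extract_all,
    hog_features,
    normalize_pssm,
    pse_pssm_features,
)
from memdsn.pipeline import extract_batch
from memdsn.pssm_io import PSSM

from conftest import random_pssm


class TestNormalize:
    def test_constant_row_maps_to_zeros(self):
        p = PSSM(id="c", scores=np.vstack([np.full(20, 5), np.arange(20)]))
        f = normalize_pssm(p).values
        np.testing.assert_array_equal(f[0], np.zeros(20))

    def test_alternating_row_is_plus_minus_one(self):
        row = np.tile([1, -1], 10)
        f = normalize_pssm(PSSM(id="a", scores=row.reshape(1, 20))).values
        np.testing.assert_allclose(f[0], row, atol=1e-12)

    def test_rows_have_mean_zero_popsd_one(self, rng):
        p = random_pssm(rng, 80)
        f = normalize_pssm(p).values
        nonconst = p.scores.std(axis=1) > 0
        np.testing.assert_allclose(f[nonconst].mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(f[nonconst].std(axis=1), 1, atol=1e-12)


class TestPsePssm:
    def test_lag_zero_is_column_means(self, small_pssm):
        norm = normalize_pssm(small_pssm)
        np.testing.assert_allclose(pse_pssm_features(norm, 0), norm.values.mean(axis=0))

    def test_identical_rows_zero_lag_terms(self):
        p = PSSM(id="i", scores=np.tile(np.arange(20), (6, 1)))
        v = pse_pssm_features(normalize_pssm(p), 1)
        np.testing.assert_array_equal(v[20:], np.zeros(20))

    def test_three_row_brute_force(self, rng):
        p = random_pssm(rng, 3)
        f = normalize_pssm(p).values
        v = pse_pssm_features(normalize_pssm(p), 1)
        expected = ((f[0] - f[1]) ** 2 + (f[1] - f[2]) ** 2) / 2
        np.testing.assert_allclose(v[20:], expected, atol=1e-12)

    def test_too_short(self):
        p = PSSM(id="s", scores=np.arange(20).reshape(1, 20))
        with pytest.raises(ValueError):
            pse_pssm_features(normalize_pssm(p), 1)


class TestAvBlock:
    def test_constant_matrix(self):
        p = PSSM(id="c", scores=np.full((37, 20), 3))
        np.testing.assert_array_equal(avblock_features(p), np.full(400, 3.0))

    def test_L20_is_row_major_flatten(self, rng):
        p = random_pssm(rng, 20)
        np.testing.assert_array_equal(avblock_features(p), p.scores.astype(float).ravel())

    def test_brute_force_block_means(self, rng):
        p = random_pssm(rng, 40)
        v = avblock_features(p)
        # direct loop with the same round-half-up boundaries
        for i in range(20):
            lo = int(np.floor(i * 40 / 20 + 0.5))
            hi = int(np.floor((i + 1) * 40 / 20 + 0.5))
            for j in range(20):
                assert v[i * 20 + j] == pytest.approx(p.scores[lo:hi, j].mean())

    def test_short_sequence_empty_blocks_zero(self):
        p = PSSM(id="s", scores=np.ones((5, 20)))
        v = avblock_features(p)
        assert len(v) == 400
        assert np.count_nonzero(v) == 5 * 20


def _sym_index(i: int, n: int) -> int:
    j = i % (2 * n)
    return j if j < n else 2 * n - 1 - j


def _dwt_level_oracle(x: np.ndarray, filt: np.ndarray) -> np.ndarray:
    """Direct evaluation of y[m] = sum_k filt[k] * x[2m+1-k] with symmetric
    (half-sample) boundary extension — the convolve-and-downsample form of
    the analysis filter bank, independent of pywt."""
    n, f = len(x), len(filt)
    out_len = (n + f - 1) // 2
    return np.array(
        [sum(filt[k] * x[_sym_index(2 * m + 1 - k, n)] for k in range(f)) for m in range(out_len)]
    )


class TestDWT:
    def test_constant_column_haar_details_vanish(self):
        p = PSSM(id="c", scores=np.full((32, 20), 7))
        cfg = FeatureConfig(wavelet_name="haar")
        v = dwt_features(p, cfg).reshape(20, 4, 2, 4)
        np.testing.assert_allclose(v[:, :, 0, :], 0, atol=1e-12)  # detail stats

    @pytest.mark.parametrize("wavelet", ["haar", "db4"])
    def test_cascade_matches_direct_convolution(self, wavelet, rng):
        w = pywt.Wavelet(wavelet)
        lo, hi = np.array(w.dec_lo), np.array(w.dec_hi)
        for _ in range(100):
            x = rng.normal(size=rng.integers(16, 90))
            approx = x
            for _level in range(4):
                cA, cD = pywt.dwt(approx, w, mode="symmetric")
                np.testing.assert_allclose(cA, _dwt_level_oracle(approx, lo), atol=1e-10)
                np.testing.assert_allclose(cD, _dwt_level_oracle(approx, hi), atol=1e-10)
                approx = cA

    def test_stats_wiring_against_manual_cascade(self, small_pssm):
        cfg = FeatureConfig()
        v = dwt_features(small_pssm, cfg).reshape(20, 4, 2, 4)
        w = pywt.Wavelet(cfg.wavelet_name)
        col = small_pssm.scores[:, 3].astype(float)
        approx = col
        for level in range(4):
            approx, detail = pywt.dwt(approx, w, mode="symmetric")
            for bi, band in enumerate((detail, approx)):
                np.testing.assert_allclose(
                    v[3, level, bi],
                    [band.mean(), band.std(), band.max(), band.min()],
                    atol=1e-12,
                )

    @pytest.mark.parametrize("L", [16, 57, 3000])
    def test_length_invariance(self, L, rng):
        assert len(dwt_features(random_pssm(rng, L))) == 640

    def test_short_signal_padded(self, rng):
        assert len(dwt_features(random_pssm(rng, 16))) == 640

    def test_bad_wavelet_name(self):
        with pytest.raises(ConfigurationError):
            FeatureConfig(wavelet_name="not-a-wavelet")


class TestDCT:
    def test_constant_matrix_closed_form(self):
        c, M = 2.5, 12
        p = PSSM(id="c", scores=np.full((M, 20), c))
        v = dct_features(p).reshape(20, 20)
        assert v[0, 0] == pytest.approx(c * np.sqrt(M * 20))
        v[0, 0] = 0
        np.testing.assert_allclose(v, 0, atol=1e-9)

    def test_orthonormality_parseval_and_inverse(self, rng):
        p = random_pssm(rng, 50)
        coeffs = scipy.fft.dctn(p.scores.astype(float), type=2, norm="ortho")
        assert np.linalg.norm(coeffs) == pytest.approx(np.linalg.norm(p.scores.astype(float)), abs=1e-8)
        back = scipy.fft.idctn(coeffs, type=2, norm="ortho")
        np.testing.assert_allclose(back, p.scores, atol=1e-8)

    @pytest.mark.parametrize("L", [5, 20, 500])
    def test_fixed_block_size(self, L, rng):
        assert len(dct_features(random_pssm(rng, L))) == 400

    def test_zero_padding_below_keep_rows(self, rng):
        p = random_pssm(rng, 5)
        v = dct_features(p).reshape(20, 20)
        np.testing.assert_array_equal(v[5:], 0)


class TestHOG:
    def test_constant_matrix_all_zero(self):
        p = PSSM(id="c", scores=np.full((25, 20), 4))
        np.testing.assert_array_equal(hog_features(p), np.zeros(250))

    def test_mass_conservation(self, rng):
        p = random_pssm(rng, 63)
        cfg = FeatureConfig(hog_l2_normalize=False)
        v = hog_features(p, cfg)
        g_vert, g_horiz = np.gradient(p.scores.astype(float))
        total = np.hypot(g_vert, g_horiz).sum()
        assert v.sum() == pytest.approx(total, abs=1e-9)

    @pytest.mark.parametrize("L", [16, 444])
    def test_length_invariance(self, L, rng):
        assert len(hog_features(random_pssm(rng, L))) == 250

    def test_needs_two_rows(self):
        with pytest.raises(ValueError):
            hog_features(PSSM(id="s", scores=np.ones((1, 20))))


class TestExtractAll:
    def test_default_layout(self, rng):
        fv = extract_all(random_pssm(rng, 100))
        assert len(fv.values) == 1730
        assert [(n, l) for n, _, l in fv.layout] == [
            ("pse_pssm", 40), ("avblock", 400), ("dwt", 640), ("dct", 400), ("hog", 250),
        ]

    def test_segments_equal_standalone_extractors(self, small_pssm):
        cfg = FeatureConfig()
        fv = extract_all(small_pssm, cfg)
        norm = normalize_pssm(small_pssm)
        np.testing.assert_array_equal(fv.segment("pse_pssm"), pse_pssm_features(norm, cfg.pse_lag))
        np.testing.assert_array_equal(fv.segment("avblock"), avblock_features(small_pssm))
        np.testing.assert_array_equal(fv.segment("dwt"), dwt_features(small_pssm, cfg))
        np.testing.assert_array_equal(fv.segment("dct"), dct_features(small_pssm, cfg))
        np.testing.assert_array_equal(fv.segment("hog"), hog_features(small_pssm, cfg))

    def test_single_entry_change_propagates(self, rng):
        a = random_pssm(rng, 44)
        scores = a.scores.copy()
        scores[17, 4] += 3
        b = PSSM(id="b", scores=scores)
        va, vb = extract_all(a), extract_all(b)
        assert not np.array_equal(va.values, vb.values)
        assert not np.array_equal(va.segment("avblock"), vb.segment("avblock"))

    @pytest.mark.parametrize("L", [16, 57, 444, 3000])
    def test_dimension_independent_of_length(self, L, rng):
        assert len(extract_all(random_pssm(rng, L)).values) == 1730

    def test_batch_permutation_equivariance(self, rng):
        pssms = [random_pssm(rng, int(L)) for L in rng.integers(16, 60, size=5)]
        X = extract_batch(pssms)
        perm = [3, 0, 4, 1, 2]
        Xp = extract_batch([pssms[i] for i in perm])
        np.testing.assert_array_equal(Xp, X[perm])
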